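"""Screen orchestration: primary hit calling, viability filtering,
concentration–response confirmation, cross-readout correlation and the
reversal-mode (de-differentiation) protocol.

The primary screen tests every compound at a single concentration (default
10 μM); compounds that inhibit myofibroblast formation by more than the
effect threshold while reducing viability by less than the viability
threshold become primary hits. Primary hits are confirmed when a full
concentration–response fit yields an uncensored IC50 below the confirmation
cut. Potencies across readouts are compared by Spearman rank correlation
with average ties and exact permutation p-values at small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import synth
from .doseresponse import CENSOR_NONE, DoseResponseFit, fit_3pl, summarize_potency
from .ipqa import PeptideQuant, normalize_to_tubulin

__all__ = [
    "ScreenConfig",
    "ScreenHit",
    "call_primary_hits",
    "confirm_hits",
    "spearman",
    "correlate_readouts",
    "run_reversal_mode",
    "run_synthetic_screen",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and protocol timing of the screening cascade."""

    primary_conc_nM: float = 10000.0
    effect_threshold_pct: float = 50.0
    viability_threshold_pct: float = 50.0
    confirmation_ic50_nM: float = 10000.0
    assay_mode: str = "prevention"  # or "reversal"
    readout_time_h: float = 48.0  # reversal protocol reads at 96 h

    def __post_init__(self) -> None:
        for t in (self.effect_threshold_pct, self.viability_threshold_pct):
            if not 0 < t <= 100:
                raise ValueError("thresholds must lie in (0, 100]")
        if self.assay_mode not in ("prevention", "reversal"):
            raise ValueError("assay_mode must be 'prevention' or 'reversal'")


@dataclass
class ScreenHit:
    compound_id: str
    percent_inhibition: float
    viability_reduction_pct: float
    viability_pass: bool
    tier: str  # "primary" | "confirmed" | "rejected"
    ic50_nM: float | None = None
    ic50_censored: bool = False


def call_primary_hits(
    effects: pd.DataFrame,
    viability: pd.DataFrame,
    cfg: ScreenConfig = ScreenConfig(),
) -> list[ScreenHit]:
    """Apply the primary-screen effect and viability filters.

    ``effects`` needs columns ``compound_id, percent_inhibition``;
    ``viability`` needs ``compound_id, viability_reduction_pct``. A
    compound above the effect threshold but failing viability is kept with
    tier ``rejected`` and its viability value — toxic actives are flagged,
    never silently dropped. A missing viability record is an error.
    """
    viab = viability.set_index("compound_id")["viability_reduction_pct"]
    hits = []
    for row in effects.itertuples():
        if row.compound_id not in viab.index:
            raise KeyError(f"no viability record for {row.compound_id}")
        v = float(viab[row.compound_id])
        ok_effect = row.percent_inhibition > cfg.effect_threshold_pct
        ok_viab = v < cfg.viability_threshold_pct
        tier = "primary" if (ok_effect and ok_viab) else "rejected"
        hits.append(
            ScreenHit(
                compound_id=row.compound_id,
                percent_inhibition=float(row.percent_inhibition),
                viability_reduction_pct=v,
                viability_pass=ok_viab,
                tier=tier if ok_effect else "rejected",
            )
        )
    return hits


def confirm_hits(
    hits: list[ScreenHit],
    fits: dict[str, DoseResponseFit],
    cfg: ScreenConfig = ScreenConfig(),
) -> list[ScreenHit]:
    """Promote primary hits with uncensored IC50 below the confirmation cut."""
    out = []
    for h in hits:
        h2 = ScreenHit(**vars(h))
        f = fits.get(h.compound_id)
        if f is not None:
            h2.ic50_censored = f.censor != CENSOR_NONE
            h2.ic50_nM = None if h2.ic50_censored else f.ec50
        if (
            h2.tier == "primary"
            and h2.ic50_nM is not None
            and h2.ic50_nM < cfg.confirmation_ic50_nM
        ):
            h2.tier = "confirmed"
        out.append(h2)
    return out


def hits_frame(hits: list[ScreenHit]) -> pd.DataFrame:
    return pd.DataFrame([vars(h) for h in hits])


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def _rank_average(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x, y, *, exact_n_max: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with a two-tailed p-value.

    Ranks use the average-ties convention; r is the Pearson correlation of
    the ranks. The p-value is an exact permutation enumeration for
    n ≤ ``exact_n_max`` and the t-distribution approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 paired values")
    rx, ry = _rank_average(x), _rank_average(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= exact_n_max:
        cnt = 0
        total = 0
        rx_c = rx - rx.mean()
        denom = math.sqrt((rx_c**2).sum())
        for perm in itertools.permutations(ry):
            p = np.asarray(perm)
            pc = p - p.mean()
            d2 = math.sqrt((pc**2).sum())
            rp = float(rx_c @ pc) / (denom * d2)
            if abs(rp) >= abs(r) - 1e-12:
                cnt += 1
            total += 1
        return r, cnt / total
    t = r * math.sqrt((n - 2) / max(1.0 - r**2, 1e-300))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def correlate_readouts(
    potencies: pd.DataFrame,
    *,
    alpha: float = 0.05,
    exclude_censored: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation of per-compound potencies across
    readouts.

    ``potencies`` is indexed by compound with one column per readout;
    censored potencies enter at their bound value unless
    ``exclude_censored`` (a companion boolean frame ``<col>_censored`` may
    flag them). Returns (r matrix, p matrix); entries with fewer than 5
    complete pairs are an error.
    """
    readouts = [c for c in potencies.columns if not c.endswith("_censored")]
    r_mat = pd.DataFrame(np.eye(len(readouts)), index=readouts, columns=readouts)
    p_mat = pd.DataFrame(np.zeros((len(readouts),) * 2), index=readouts, columns=readouts)
    for a, b in itertools.combinations(readouts, 2):
        sub = potencies[[a, b]].dropna()
        if exclude_censored:
            for c in (a, b):
                flag = f"{c}_censored"
                if flag in potencies.columns:
                    sub = sub[~potencies.loc[sub.index, flag].astype(bool)]
        if len(sub) < 5:
            raise ValueError(f"fewer than 5 paired potencies for {a} vs {b}")
        r, p = spearman(sub[a].to_numpy(), sub[b].to_numpy())
        r_mat.loc[a, b] = r_mat.loc[b, a] = r
        p_mat.loc[a, b] = p_mat.loc[b, a] = p
    return r_mat, p_mat


# ---------------------------------------------------------------------------
# Reversal (de-differentiation) mode
# ---------------------------------------------------------------------------


def run_reversal_mode(
    layout: synth.PlateLayout,
    cfg: ScreenConfig,
    registry: synth.CompoundRegistry | None = None,
    seed: int = 0,
    *,
    n_cells: int = 400,
    dp: synth.DifferentiationParams = synth.DifferentiationParams(),
    mp: synth.MsmsParams = synth.MsmsParams(),
) -> tuple[pd.DataFrame, list[PeptideQuant]]:
    """Simulate the reversal protocol on a plate and compute its readouts.

    Protocol: TGF-β1 from 0–24 h, washout, compound from 24–96 h, read at
    96 h. Differentiation persists in vehicle wells; only reversal-capable
    compounds move wells back toward the fibroblast state. Returns the
    per-well effect table (reversal scale: 0% = persisting myofibroblasts,
    100% = fully reverted) and tubulin-normalized peptide quants.
    """
    if cfg.assay_mode != "reversal":
        raise ValueError("config is not in reversal mode")
    if layout.mode != "reversal":
        raise ValueError("a prevention-mode plate cannot run the reversal protocol")

    master = np.random.SeedSequence(seed)
    seeds = master.spawn(len(layout.wells))
    rng_seeds = {w: s for w, s in zip(layout.wells["well"], seeds)}

    rows = []
    quants = []
    f_vehicle = dp.f_max  # persisting differentiated state
    f_floor = dp.f_min
    for _, wrow in layout.wells.iterrows():
        rec = None
        cid = wrow["compound_id"]
        if cid is not None and not pd.isna(cid) and registry is not None:
            rec = registry.get(cid)
        role = wrow["role"]
        if role == "pos_control":
            frac = f_floor  # never stimulated
        else:
            frac = synth.reversal_myo_fraction(rec, wrow["conc_nM"], dp)
        rng = np.random.default_rng(rng_seeds[wrow["well"]])
        f_obs = rng.binomial(n_cells, min(max(frac, 0.0), 1.0)) / n_cells
        effect = 100.0 * (f_vehicle - f_obs) / (f_vehicle - f_floor)
        rows.append(
            {
                "well": wrow["well"], "role": role, "compound_id": cid,
                "conc_nM": wrow["conc_nM"], "myo_fraction": f_obs,
                "percent_effect": effect,
            }
        )
        if role == "pos_control":
            q = synth.simulate_msms_well(
                0.0, None, 0.0, n_cells, rng_seeds[wrow["well"]], mp,
                well=wrow["well"],
            )
        else:
            q = synth.simulate_msms_reversal_well(
                rec, wrow["conc_nM"], n_cells, rng_seeds[wrow["well"]], mp, dp,
                well=wrow["well"],
            )
        quants.append(q)
    return pd.DataFrame(rows), normalize_to_tubulin(quants)


# ---------------------------------------------------------------------------
# End-to-end synthetic screen
# ---------------------------------------------------------------------------


def run_synthetic_screen(
    registry: synth.CompoundRegistry,
    cfg: ScreenConfig = ScreenConfig(),
    seed: int = 0,
    *,
    n_cells: int = 400,
    confirmation_concs: np.ndarray | None = None,
    dp: synth.DifferentiationParams = synth.DifferentiationParams(),
) -> pd.DataFrame:
    """Primary screen + confirmation on a synthetic library; one row per
    compound with tier assignment, for validation against the registry."""
    readouts = synth.simulate_screen_readouts(
        registry, cfg.primary_conc_nM, seed, n_cells=n_cells, dp=dp
    )
    effects = readouts[["compound_id", "percent_inhibition"]]
    viability = readouts[["compound_id", "viability_reduction_pct"]]
    hits = call_primary_hits(effects, viability, cfg)

    if confirmation_concs is None:
        confirmation_concs = 30000.0 / 3.0 ** np.arange(8)  # 30 μM, 3-fold steps
    ss = np.random.SeedSequence(seed + 1)
    children = iter(ss.spawn(len(hits)))
    fits: dict[str, DoseResponseFit] = {}
    for h in hits:
        child = next(children)
        if h.tier != "primary":
            continue
        series = synth.simulate_confirmation_series(
            registry.get(h.compound_id), confirmation_concs, child,
            n_cells=n_cells, dp=dp,
        )
        fits[h.compound_id] = fit_3pl(
            np.log10(series["conc_nM"]), series["percent_inhibition"]
        )
    final = confirm_hits(hits, fits, cfg)
    df = hits_frame(final)
    truth = registry.table.set_index("compound_id")["active"]
    df["true_active"] = df["compound_id"].map(truth).astype(bool)
    return df
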