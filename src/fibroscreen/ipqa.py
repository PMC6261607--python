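"""Impedance and protein-quantification assay (IPQA) computations.

Two halves, reflecting the multiplexed readout of the label-free arm of the
screen:

* impedance trace processing — normalization of raw real-time cell-analysis
  (RTCA) cell-index traces to the compound-addition time point, subtraction
  of the non-stimulated baseline response, time-point readouts and nadir
  detection;
* MRM surrogate-peptide chemistry — monoisotopic precursor and b/y fragment
  m/z calculation for the tryptic peptides used to quantify COL1A1, α-SMA
  (ACTA) and α-tubulin (TBA1A), transition-table construction and
  tubulin-ratio normalization of peak areas.

m/z values are computed from first principles (residue masses + water +
protons) so they can be checked against an independent summation oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MONOISOTOPIC_RESIDUE_MASS",
    "PROTON_MASS",
    "WATER_MASS",
    "CARBAMIDOMETHYL_SHIFT",
    "Peptide",
    "MRMTransition",
    "PeptideQuant",
    "ImpedanceTrace",
    "FIBROSIS_PANEL",
    "peptide_mass",
    "peptide_mz",
    "fragment_mz",
    "build_mrm_table",
    "normalize_to_tubulin",
    "preprocess_trace",
    "trace_response",
    "find_nadir",
]

# Monoisotopic residue (amino-acid minus water) masses, Da.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

PROTON_MASS = 1.007276  # Da, mass of H+
WATER_MASS = 18.0105646  # Da, monoisotopic H2O
CARBAMIDOMETHYL_SHIFT = 57.02146  # Da, fixed Cys derivatization (+C2H3NO)


@dataclass(frozen=True)
class Peptide:
    """A surrogate tryptic peptide monitored by MRM.

    Parameters
    ----------
    sequence : str
        Residue sequence in single-letter code.
    charge : int
        Precursor charge state (positive).
    protein : str
        Label of the protein the peptide quantifies (e.g. ``"COL1A1"``).
    """

    sequence: str
    charge: int = 2
    protein: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - set(MONOISOTOPIC_RESIDUE_MASS)
        if bad:
            raise ValueError(f"unknown residue symbol(s): {sorted(bad)}")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")


@dataclass(frozen=True)
class MRMTransition:
    """One parent → product ion transition of an MRM method."""

    peptide: Peptide
    precursor_mz: float
    fragment: str  # e.g. "y8"
    product_mz: float
    protein: str


@dataclass
class PeptideQuant:
    """Peak areas for the three-protein panel in one well, plus ratios.

    Ratios to tubulin are populated by :func:`normalize_to_tubulin`; they
    remove the shared cell-number factor from the COL1A1 and ACTA areas.
    """

    well: str
    area_col1a1: float
    area_acta: float
    area_tba1a: float
    ratio_col1: float | None = None
    ratio_acta: float | None = None
    flagged: bool = False


def peptide_mass(sequence: str, *, carbamidomethyl: bool = False) -> float:
    """Neutral monoisotopic peptide mass: residue masses + one water."""
    try:
        m = sum(MONOISOTOPIC_RESIDUE_MASS[a] for a in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue symbol: {exc.args[0]!r}") from exc
    if carbamidomethyl:
        m += CARBAMIDOMETHYL_SHIFT * sequence.count("C")
    return m + WATER_MASS


def peptide_mz(p: Peptide, *, carbamidomethyl: bool = False) -> float:
    """Precursor m/z of a protonated peptide: (M + z·mH+)/z."""
    m = peptide_mass(p.sequence, carbamidomethyl=carbamidomethyl)
    return (m + p.charge * PROTON_MASS) / p.charge


def fragment_mz(
    p: Peptide, ion: str, z: int = 1, *, carbamidomethyl: bool = False
) -> float:
    """m/z of a b- or y-series fragment ion.

    ``ion`` is a series letter plus index, e.g. ``"y8"`` or ``"b3"``.
    y_n carries the n C-terminal residues plus water; b_n carries the n
    N-terminal residues (no water). Both are protonated with z protons.
    """
    if z < 1:
        raise ValueError("fragment charge must be >= 1")
    series, idx_s = ion[0], ion[1:]
    if series not in ("b", "y") or not idx_s.isdigit():
        raise ValueError(f"fragment ion spec must be b<i> or y<i>, got {ion!r}")
    n = int(idx_s)
    if not 1 <= n < len(p.sequence):
        raise ValueError(
            f"fragment index {n} out of range for peptide of length {len(p.sequence)}"
        )
    part = p.sequence[-n:] if series == "y" else p.sequence[:n]
    m = sum(MONOISOTOPIC_RESIDUE_MASS[a] for a in part)
    if carbamidomethyl:
        m += CARBAMIDOMETHYL_SHIFT * part.count("C")
    if series == "y":
        m += WATER_MASS
    return (m + z * PROTON_MASS) / z


# The three-protein quantification panel: doubly charged tryptic precursors
# and the singly charged y ions monitored on the triple quadrupole.
FIBROSIS_PANEL: list[tuple[Peptide, str]] = [
    (Peptide("GVVGLPGQR", 2, "COL1A1"), "y4"),
    (Peptide("GYSFVTTAER", 2, "ACTA"), "y8"),
    (Peptide("DVNAAIATIK", 2, "TBA1A"), "y8"),
]


def build_mrm_table(
    peptides_fragments: list[tuple[Peptide, str]] | None = None,
    *,
    annotations: dict[str, tuple[float, float]] | None = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Build an MRM transition table for a list of (peptide, fragment) pairs.

    Defaults to :data:`FIBROSIS_PANEL`. ``annotations`` optionally maps a
    peptide sequence to externally supplied (precursor, product) m/z values
    — for instance instrument-tuned settings — which are reported alongside
    the computed values with a mismatch flag at ``decimals`` precision.
    """
    if peptides_fragments is None:
        peptides_fragments = FIBROSIS_PANEL
    rows = []
    for pep, frag in peptides_fragments:
        prec = round(peptide_mz(pep), decimals)
        prod = round(fragment_mz(pep, frag, 1), decimals)
        row = {
            "protein": pep.protein,
            "peptide": pep.sequence,
            "z": pep.charge,
            "precursor_mz": prec,
            "fragment": frag,
            "product_mz": prod,
        }
        if annotations and pep.sequence in annotations:
            ref_prec, ref_prod = annotations[pep.sequence]
            row["ref_precursor_mz"] = ref_prec
            row["ref_product_mz"] = ref_prod
            row["matches_ref"] = (
                abs(prec - ref_prec) < 1.5 * 10 ** -decimals
                and abs(prod - ref_prod) < 1.5 * 10 ** -decimals
            )
        rows.append(row)
    cols = ["protein", "peptide", "z", "precursor_mz", "fragment", "product_mz"]
    if annotations:
        cols += ["ref_precursor_mz", "ref_product_mz", "matches_ref"]
    return pd.DataFrame(rows, columns=cols if rows else None)


def normalize_to_tubulin(quants: list[PeptideQuant]) -> list[PeptideQuant]:
    """Populate COL1A1/TBA1A and ACTA/TBA1A ratios, preserving raw areas.

    Wells with non-positive tubulin area are flagged and their ratios left
    undefined rather than raising — a failed well should not abort a plate.
    """
    out = []
    for q in quants:
        if q.area_tba1a > 0:
            out.append(
                replace(
                    q,
                    ratio_col1=q.area_col1a1 / q.area_tba1a,
                    ratio_acta=q.area_acta / q.area_tba1a,
                    flagged=False,
                )
            )
        else:
            out.append(replace(q, ratio_col1=None, ratio_acta=None, flagged=True))
    return out


# ---------------------------------------------------------------------------
# Impedance traces
# ---------------------------------------------------------------------------

RAW = "raw"
NORMALIZED = "normalized"
BASELINE_SUBTRACTED = "baseline_subtracted"


@dataclass
class ImpedanceTrace:
    """A time-indexed cell-index trace for one well.

    ``state`` tracks the processing stage: ``raw`` → ``normalized`` (divided
    by the value at the compound-addition reference time, so the trace is
    1.0 there) → ``baseline_subtracted`` (normalized baseline mean removed).
    """

    well: str
    times: np.ndarray
    values: np.ndarray
    state: str = RAW
    t_ref: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equally long")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def value_at(self, t: float) -> float:
        if not self.times[0] <= t <= self.times[-1]:
            raise ValueError(f"t={t} outside sampled range "
                             f"[{self.times[0]}, {self.times[-1]}]")
        return float(np.interp(t, self.times, self.values))


def preprocess_trace(
    raw: ImpedanceTrace,
    t_ref: float = 0.0,
    baseline_mean: ImpedanceTrace | None = None,
    *,
    mode: str = "divide",
) -> ImpedanceTrace:
    """Normalize a trace to the compound-addition time point, then subtract
    the baseline (vehicle, non-stimulated) mean response.

    ``mode="divide"`` (RTCA convention) divides by the value at ``t_ref`` so
    the normalized trace is exactly 1.0 there; ``mode="subtract"`` subtracts
    that value instead (trace is 0.0 at the reference). The baseline trace
    is normalized identically before subtraction and linearly resampled onto
    the trace's time grid if the grids differ.

    Already-normalized input with the same ``t_ref`` passes through
    unchanged up to baseline subtraction (idempotent normalization).
    """
    if mode not in ("divide", "subtract"):
        raise ValueError("mode must be 'divide' or 'subtract'")
    if not raw.times[0] <= t_ref <= raw.times[-1]:
        raise ValueError("t_ref outside the sampled time range")

    if raw.state == RAW:
        ref = raw.value_at(t_ref)
        if mode == "divide":
            if ref <= 0:
                raise ValueError(
                    f"cell index at t_ref={t_ref} is {ref:.4g}; cannot normalize"
                )
            vals = raw.values / ref
        else:
            vals = raw.values - ref
        norm = ImpedanceTrace(raw.well, raw.times, vals, NORMALIZED, t_ref)
    elif raw.state == NORMALIZED:
        if raw.t_ref is not None and raw.t_ref != t_ref:
            raise ValueError("trace already normalized to a different t_ref")
        norm = raw
    else:
        raise ValueError("trace is already baseline-subtracted")

    if baseline_mean is None:
        return norm

    if baseline_mean.state == RAW:
        baseline_mean = preprocess_trace(baseline_mean, t_ref, None, mode=mode)
    base_vals = np.interp(norm.times, baseline_mean.times, baseline_mean.values)
    return ImpedanceTrace(
        norm.well, norm.times, norm.values - base_vals, BASELINE_SUBTRACTED, t_ref
    )


def baseline_mean_trace(traces: list[ImpedanceTrace], t_ref: float = 0.0,
                        *, mode: str = "divide") -> ImpedanceTrace:
    """Normalize baseline-well replicates and average them point-wise."""
    if not traces:
        raise ValueError("need at least one baseline trace")
    normed = [preprocess_trace(t, t_ref, None, mode=mode) for t in traces]
    grid = normed[0].times
    stack = np.vstack([np.interp(grid, t.times, t.values) for t in normed])
    return ImpedanceTrace("baseline_mean", grid, stack.mean(axis=0),
                          NORMALIZED, t_ref)


def trace_response(trace: ImpedanceTrace, t: float = 20.0) -> float:
    """Baseline-subtracted impedance response at time ``t`` (default 20 h
    post stimulation; reversal-mode analyses read at 72 h).

    Linear interpolation between samples; ``t`` outside the sampled range is
    an error rather than an extrapolation.
    """
    if trace.state != BASELINE_SUBTRACTED:
        raise ValueError("trace must be baseline-subtracted before readout")
    return trace.value_at(t)


def find_nadir(
    trace: ImpedanceTrace, window: tuple[float, float]
) -> tuple[float, float]:
    """Time and depth of the minimum within ``window`` (hours).

    Relaxation responses show a concentration-dependent dip shortly after
    compound addition; this locates it. Ties resolve to the earliest time.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty nadir window")
    if lo < trace.times[0] or hi > trace.times[-1]:
        raise ValueError("window outside the sampled time range")
    sel = (trace.times >= lo) & (trace.times <= hi)
    if not sel.any():
        raise ValueError("no samples inside the window")
    t_w, v_w = trace.times[sel], trace.values[sel]
    i = int(np.argmin(v_w))  # argmin returns the first minimum: earliest tie
    return float(t_w[i]), float(v_w[i])
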