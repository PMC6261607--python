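"""Synthetic plate generator for the fibroblast-to-myofibroblast screen.

Produces every input the analysis stages consume, with ground truth:

* plate layouts (96/384-well) with negative/positive control, baseline and
  sample wells;
* four-channel fluorescence fields (DAPI, α-SMA, fibronectin, whole-cell)
  rendering two cell phenotypes — quiescent fibroblasts with diffuse marker
  signal, and myofibroblasts with bright α-SMA stress fibers and punctate
  fibronectin fibrils — so intensity, texture and granularity all carry
  class information;
* impedance (cell-index) time series with a TGF-β1 dose-dependent transient
  rise that declines after ~24 h, compound inhibition, an optional
  early relaxation dip, and AR(1) noise;
* MRM peak-area triples (COL1A1, ACTA, TBA1A) where marker/tubulin ratios
  follow a Hill curve of TGF-β1 dose (~3-fold induction, EC50 0.07 and
  0.05 ng/ml respectively);
* compound registries with known potencies, efficacies and toxicity, the
  ground truth for hit-caller validation.

The myofibroblast fraction of a well follows one logistic dose rule shared
by the imaging and protein readouts, so the two assay arms are mutually
consistent. All randomness flows from explicit seeds via hierarchical
``SeedSequence`` splitting: identical seeds reproduce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .ipqa import PeptideQuant

__all__ = [
    "LayoutError",
    "PhenotypeParams",
    "FIBROBLAST",
    "MYOFIBROBLAST",
    "PlateDesign",
    "PlateLayout",
    "generate_plate_layout",
    "hca_design",
    "ipqa_design",
    "CompoundRecord",
    "CompoundRegistry",
    "generate_compound_library",
    "inhibition_remaining",
    "DifferentiationParams",
    "myofibroblast_fraction",
    "reversal_myo_fraction",
    "SimulatedField",
    "simulate_cell_field",
    "simulate_hca_plate",
    "KineticParams",
    "pulse_shape",
    "tgf_amplitude",
    "relaxation_shape",
    "simulate_impedance_trace",
    "MsmsParams",
    "simulate_msms_well",
    "simulate_msms_reversal_well",
    "simulate_screen_readouts",
    "simulate_confirmation_series",
]


class LayoutError(ValueError):
    """Raised for invalid plate designs (e.g. a missing control role)."""


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeParams:
    """Rendering parameters of one cell phenotype.

    Intensities are mean in-mask values in arbitrary 16-bit units before
    noise and background; the renderer rescales each cell so the mask mean
    matches exactly, which makes the configured class contrast directly
    verifiable by averaging over ground-truth masks.
    """

    label: str
    cell_area_px2: float
    eccentricity: tuple[float, float]
    sma_mean: float
    fiber_count: int
    fiber_width_px: float
    fn_mean: float
    fibril_density: float
    noise_cv: float
    brightness_sd: float = 0.4  # per-cell log-normal marker brightness
    fiber_gain: float = 4.0  # fiber peak relative to diffuse signal
    area_sd: float = 0.3  # per-cell log-normal spread of cell area

    def __post_init__(self) -> None:
        if not (0 <= self.sma_mean <= 65535 and 0 <= self.fn_mean <= 65535):
            raise ValueError("mean intensities must lie in [0, 65535]")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        lo, hi = self.eccentricity
        if not (0 <= lo <= hi < 1):
            raise ValueError("eccentricity range must satisfy 0 <= lo <= hi < 1")


FIBROBLAST = PhenotypeParams(
    label="fibroblast", cell_area_px2=150.0, eccentricity=(0.3, 0.85),
    sma_mean=700.0, fiber_count=2, fiber_width_px=1.5,
    fn_mean=550.0, fibril_density=0.10, noise_cv=0.15,
    brightness_sd=0.55, fiber_gain=1.0, area_sd=0.35,
)
MYOFIBROBLAST = PhenotypeParams(
    label="myofibroblast", cell_area_px2=240.0, eccentricity=(0.45, 0.9),
    sma_mean=2100.0, fiber_count=6, fiber_width_px=1.5,
    fn_mean=1500.0, fibril_density=0.30, noise_cv=0.15,
    brightness_sd=0.55, fiber_gain=3.5, area_sd=0.35,
)

WELL_BRIGHTNESS_SD = 0.15  # per-well staining/illumination log-normal factor
NUCLEUS_AREA_PX2 = 40.0  # class-independent nucleus size
NUCLEUS_AREA_SD = 0.25

BACKGROUND_LEVEL = 100.0
READ_NOISE_SD = 20.0
NUCLEUS_INTENSITY = 3000.0
WHOLECELL_INTENSITY = 1500.0
CHANNELS = ("dapi", "sma", "fn", "wholecell")


# ---------------------------------------------------------------------------
# Plate layouts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateDesign:
    """Column-based well-role assignment for a plate.

    Negative controls are TGF-β1-stimulated (5 ng/ml), compound-free wells
    defining 0% compound effect; positive controls are unstimulated wells
    defining 100% effect. Baseline wells (vehicle, unstimulated) anchor
    impedance baseline subtraction. ``compounds`` fills sample wells
    row-major with (compound_id, concentration nM) pairs.
    """

    neg_control_cols: tuple[int, ...]
    pos_control_cols: tuple[int, ...]
    baseline_cols: tuple[int, ...] = ()
    neg_tgf_ng_ml: float = 5.0
    sample_tgf_ng_ml: float = 5.0
    mode: str = "prevention"
    compounds: tuple[tuple[str, float], ...] = ()


def hca_design(compounds: Iterable[tuple[str, float]] = ()) -> PlateDesign:
    """Default 384-well imaging design: 32 control wells per role."""
    return PlateDesign(
        neg_control_cols=(1, 23), pos_control_cols=(2, 24),
        compounds=tuple(compounds),
    )


def ipqa_design(compounds: Iterable[tuple[str, float]] = ()) -> PlateDesign:
    """Default 96-well impedance/MRM design with baseline wells."""
    return PlateDesign(
        neg_control_cols=(1,), pos_control_cols=(12,), baseline_cols=(2,),
        compounds=tuple(compounds),
    )


@dataclass
class PlateLayout:
    rows: int
    cols: int
    wells: pd.DataFrame  # well, row, col, role, compound_id, conc_nM, tgf_ng_ml, replicate
    mode: str = "prevention"

    def wells_of_role(self, role: str) -> pd.DataFrame:
        return self.wells[self.wells["role"] == role]

    def to_csv(self, path) -> None:
        self.wells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PlateLayout":
        df = pd.read_csv(path)
        rows = df["row"].max() + 1
        cols = df["col"].max() + 1
        return cls(int(rows), int(cols), df)


def well_name(row: int, col: int) -> str:
    """0-based (row, col) to plate coordinate, e.g. (0, 0) -> 'A01'."""
    letters = "ABCDEFGHIJKLMNOP"
    return f"{letters[row]}{col + 1:02d}"


def generate_plate_layout(rows: int, cols: int, design: PlateDesign) -> PlateLayout:
    """Build a complete well grid from a column-based design.

    Deterministic for a given design. Raises :class:`LayoutError` when a
    control role has no wells or a column index falls outside the plate.
    """
    if rows * cols not in (96, 384):
        raise LayoutError("standard layouts are 96 (8x12) or 384 (16x24) wells")
    for c in (*design.neg_control_cols, *design.pos_control_cols, *design.baseline_cols):
        if not 1 <= c <= cols:
            raise LayoutError(f"design column {c} outside 1..{cols}")
    if not design.neg_control_cols or not design.pos_control_cols:
        raise LayoutError("design must name at least one well of each control role")

    role_of_col: dict[int, str] = {}
    for c in design.neg_control_cols:
        role_of_col[c] = "neg_control"
    for c in design.pos_control_cols:
        role_of_col[c] = "pos_control"
    for c in design.baseline_cols:
        role_of_col[c] = "baseline"

    records = []
    rep_counter: dict[tuple, int] = {}
    compound_iter = iter(design.compounds)
    for r in range(rows):
        for c in range(1, cols + 1):
            role = role_of_col.get(c, "sample")
            compound_id, conc = None, 0.0
            if role == "neg_control":
                tgf = design.neg_tgf_ng_ml
            elif role in ("pos_control", "baseline"):
                tgf = 0.0
            else:
                tgf = design.sample_tgf_ng_ml
                nxt = next(compound_iter, None)
                if nxt is not None:
                    compound_id, conc = nxt
            key = (role, compound_id, conc)
            rep = rep_counter.get(key, 0)
            rep_counter[key] = rep + 1
            records.append(
                {
                    "well": well_name(r, c - 1), "row": r, "col": c - 1,
                    "role": role, "compound_id": compound_id, "conc_nM": conc,
                    "tgf_ng_ml": tgf, "replicate": rep,
                }
            )
    return PlateLayout(rows, cols, pd.DataFrame(records), mode=design.mode)


# ---------------------------------------------------------------------------
# Compound registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    active: bool
    ic50_nM: float | None
    efficacy: float
    hill: float
    toxic: bool
    tox_ec50_nM: float | None
    reverses: bool = False
    relax_depth: float = 0.0


class CompoundRegistry:
    """Ground-truth compound table: potency, efficacy, toxicity, reversal."""

    COLUMNS = [
        "compound_id", "active", "true_ic50_nM", "efficacy", "hill",
        "toxic", "tox_ec50_nM", "reverses", "relax_depth",
    ]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"registry table missing columns: {sorted(missing)}")
        act = table[table["active"]]
        if (act["true_ic50_nM"] <= 0).any():
            raise ValueError("active compounds must have IC50 > 0")
        if not act["efficacy"].between(0, 1).all():
            raise ValueError("efficacy must lie in [0, 1]")
        self.table = table.reset_index(drop=True)
        self._by_id = {r.compound_id: self._record(r) for r in table.itertuples()}

    @staticmethod
    def _record(r) -> CompoundRecord:
        return CompoundRecord(
            compound_id=r.compound_id, active=bool(r.active),
            ic50_nM=None if pd.isna(r.true_ic50_nM) else float(r.true_ic50_nM),
            efficacy=float(r.efficacy), hill=float(r.hill),
            toxic=bool(r.toxic),
            tox_ec50_nM=None if pd.isna(r.tox_ec50_nM) else float(r.tox_ec50_nM),
            reverses=bool(r.reverses), relax_depth=float(r.relax_depth),
        )

    def get(self, compound_id: str) -> CompoundRecord:
        return self._by_id[compound_id]

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return iter(self._by_id.values())

    @property
    def actives(self) -> list[str]:
        return list(self.table.loc[self.table["active"], "compound_id"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CompoundRegistry":
        return cls(pd.read_csv(path))


def generate_compound_library(
    n: int,
    frac_active: float,
    potency_range: tuple[float, float] = (10.0, 50000.0),
    seed: int = 0,
    *,
    efficacy_range: tuple[float, float] = (0.8, 1.0),
    frac_toxic: float = 0.05,
    tox_range: tuple[float, float] = (2000.0, 100000.0),
    frac_reversers: float = 0.0,
) -> CompoundRegistry:
    """Generate a library with exactly ``round(n * frac_active)`` actives.

    Potencies are log-uniform over ``potency_range`` (nM). Toxicity flags
    are assigned among inactives, so the active set is the uncontaminated
    positive class for recall/false-positive accounting. Reproducible from
    ``seed``.
    """
    if not 0 <= frac_active <= 1:
        raise ValueError("frac_active must lie in [0, 1]")
    n_active = round(n * frac_active)
    lo, hi = potency_range
    if n_active > 0 and not 0 < lo < hi:
        raise ValueError("potency range must be a non-empty positive interval")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    active = np.zeros(n, dtype=bool)
    active[order[:n_active]] = True

    ic50 = np.full(n, np.nan)
    ic50[active] = 10 ** rng.uniform(math.log10(lo), math.log10(hi), n_active)
    eff = np.ones(n)
    eff[active] = rng.uniform(*efficacy_range, n_active)
    reverses = np.zeros(n, dtype=bool)
    if frac_reversers > 0 and n_active > 0:
        idx = np.flatnonzero(active)
        k = round(n_active * frac_reversers)
        reverses[rng.choice(idx, size=k, replace=False)] = True

    inactive_idx = np.flatnonzero(~active)
    toxic = np.zeros(n, dtype=bool)
    n_tox = round(len(inactive_idx) * frac_toxic)
    if n_tox > 0:
        toxic[rng.choice(inactive_idx, size=n_tox, replace=False)] = True
    tox_ec50 = np.full(n, np.nan)
    tox_ec50[toxic] = 10 ** rng.uniform(
        math.log10(tox_range[0]), math.log10(tox_range[1]), int(toxic.sum())
    )

    table = pd.DataFrame(
        {
            "compound_id": [f"C{i + 1:04d}" for i in range(n)],
            "active": active,
            "true_ic50_nM": ic50,
            "efficacy": eff,
            "hill": np.ones(n),
            "toxic": toxic,
            "tox_ec50_nM": tox_ec50,
            "reverses": reverses,
            "relax_depth": np.zeros(n),
        }
    )
    return CompoundRegistry(table)


def inhibition_remaining(
    conc_nM: float, compound: CompoundRecord | None
) -> float:
    """Fraction of the TGF-β1 response remaining under a compound.

    Three-parameter-logistic occupancy: at the compound's true IC50 with
    full efficacy, exactly half the response remains.
    """
    if compound is None or not compound.active or conc_nM <= 0:
        return 1.0
    occ = conc_nM**compound.hill / (
        conc_nM**compound.hill + compound.ic50_nM**compound.hill
    )
    return 1.0 - compound.efficacy * occ


# ---------------------------------------------------------------------------
# Differentiation dose rule (shared by imaging and protein readouts)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DifferentiationParams:
    """Hill curve mapping TGF-β1 dose to the myofibroblast fraction.

    EC50 matches the α-SMA protein induction midpoint so the imaging and
    MRM ground truths are mutually consistent; the fraction is 0 with no
    stimulation (pure fibroblast population) and saturates at ``f_max``.
    """

    ec50_ng_ml: float = 0.07
    hill: float = 1.0
    f_min: float = 0.0
    f_max: float = 1.0
    dose_jitter_cv: float = 0.10
    frac_jitter_sd: float = 0.02  # well-level sd of the realized fraction


def _hill(x: float, ec50: float, h: float) -> float:
    if x <= 0:
        return 0.0
    return x**h / (x**h + ec50**h)


def myofibroblast_fraction(
    tgf_dose: float,
    compound: CompoundRecord | None = None,
    conc_nM: float = 0.0,
    dp: DifferentiationParams = DifferentiationParams(),
    rng: np.random.Generator | None = None,
) -> float:
    """Expected myofibroblast fraction of a prevention-mode well.

    ``rng`` enables well-to-well biological variability as multiplicative
    log-normal jitter on the effective dose; omit it for the noiseless
    expectation.
    """
    dose = float(tgf_dose)
    if rng is not None and dp.dose_jitter_cv > 0 and dose > 0:
        dose *= float(rng.lognormal(0.0, dp.dose_jitter_cv))
    f = dp.f_min + (dp.f_max - dp.f_min) * _hill(dose, dp.ec50_ng_ml, dp.hill)
    f *= inhibition_remaining(conc_nM, compound)
    if rng is not None and dp.frac_jitter_sd > 0:
        f = float(np.clip(f + rng.normal(0.0, dp.frac_jitter_sd), 0.0, 1.0))
    return f


def reversal_myo_fraction(
    compound: CompoundRecord | None,
    conc_nM: float,
    dp: DifferentiationParams = DifferentiationParams(),
) -> float:
    """Myofibroblast fraction after washout in reversal (de-differentiation)
    mode: the differentiated state persists unless a reversal-capable
    compound drives it back toward the fibroblast floor."""
    f = dp.f_max
    if compound is not None and compound.active and compound.reverses and conc_nM > 0:
        occ = conc_nM**compound.hill / (
            conc_nM**compound.hill + compound.ic50_nM**compound.hill
        )
        f = dp.f_max - (dp.f_max - dp.f_min) * compound.efficacy * occ
    return f


# ---------------------------------------------------------------------------
# Image fields
# ---------------------------------------------------------------------------


@dataclass
class SimulatedField:
    """One rendered well: image stack, ground truth and label rasters."""

    well: str
    image: np.ndarray  # (4, H, W) uint16, channel order CHANNELS
    truth: pd.DataFrame  # well, cell_id, x, y, class
    cell_labels: np.ndarray  # int32 label raster, 0 = background
    nucleus_labels: np.ndarray
    myo_fraction: float  # expected fraction used for label sampling


def _cell_crop(params: PhenotypeParams, rng: np.random.Generator, channel: str,
               mask: np.ndarray, a: float, b: float, theta: float,
               brightness: float = 1.0) -> np.ndarray:
    """Render one cell's marker signal into a crop; the in-mask mean equals
    the configured mean times the cell's brightness factor exactly after
    blurring (pattern is rescaled post-blur)."""
    h, w = mask.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    target = (params.sma_mean if channel == "sma" else params.fn_mean) * brightness
    if target <= 0:
        return np.zeros_like(mask, dtype=float)
    pattern = mask.astype(float)

    n_fibers = int(rng.poisson(params.fiber_count)) if params.fiber_count else 0
    if params.fiber_count >= 3:
        n_fibers = max(n_fibers, 1)  # differentiated cells keep >= 1 fiber
    if channel == "sma" and n_fibers > 0:
        fibers = np.zeros_like(pattern)
        for _ in range(n_fibers):
            ang = theta + rng.uniform(-0.35, 0.35)
            off = rng.uniform(-0.6, 0.6) * b
            dy, dx = math.sin(ang), math.cos(ang)
            oy, ox = math.cos(ang) * off, -math.sin(ang) * off
            L = a + 2
            r0 = int(round(cy + oy - dy * L)); c0 = int(round(cx + ox - dx * L))
            r1 = int(round(cy + oy + dy * L)); c1 = int(round(cx + ox + dx * L))
            rr, cc = draw_line(
                np.clip(r0, 0, h - 1), np.clip(c0, 0, w - 1),
                np.clip(r1, 0, h - 1), np.clip(c1, 0, w - 1),
            )
            fibers[rr, cc] = 1.0
        if params.fiber_width_px > 1:
            it = max(1, int(round(params.fiber_width_px / 2)))
            fibers = ndi.grey_dilation(fibers, size=(it * 2 - 1, it * 2 - 1))
        pattern = pattern * (0.4 + params.fiber_gain * fibers)
    elif channel == "fn" and params.fibril_density > 0:
        dots = (rng.random(mask.shape) < params.fibril_density).astype(float)
        dots = ndi.grey_dilation(dots, size=(2, 2))
        pattern = pattern * (0.4 + 3.0 * dots)
    else:
        # Diffuse low-contrast signal with mild spatial variation.
        texture = ndi.gaussian_filter(rng.random(mask.shape), 1.5)
        pattern = pattern * (0.8 + 0.4 * texture)

    pattern = ndi.gaussian_filter(pattern * mask, 0.8)
    in_mask = pattern[mask > 0]
    m = in_mask.mean() if in_mask.size else 0.0
    if m <= 0:
        return np.zeros_like(pattern)
    return pattern * (target / m)


def simulate_cell_field(
    well: Mapping | str,
    n_cells: int,
    params: tuple[PhenotypeParams, PhenotypeParams] = (FIBROBLAST, MYOFIBROBLAST),
    seed: int | np.random.SeedSequence = 0,
    *,
    shape: tuple[int, int] = (384, 384),
    registry: CompoundRegistry | None = None,
    myo_fraction: float | None = None,
    dp: DifferentiationParams = DifferentiationParams(),
    noise: bool = True,
) -> SimulatedField:
    """Render one imaged field of a well with per-cell ground truth.

    ``well`` is either a layout row (mapping with ``tgf_ng_ml``,
    ``compound_id``, ``conc_nM``) from which the myofibroblast fraction is
    derived via the logistic dose rule, or a bare well name when
    ``myo_fraction`` is given explicitly.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    fib, myo = params
    if myo.sma_mean <= fib.sma_mean:
        raise ValueError("myofibroblast α-SMA mean must exceed the fibroblast mean")

    rng = np.random.default_rng(seed)
    if isinstance(well, str):
        well_id = well
        if myo_fraction is None:
            raise ValueError("myo_fraction required when well is a bare name")
        frac = myo_fraction
    else:
        well_id = str(well["well"])
        if myo_fraction is not None:
            frac = myo_fraction
        else:
            comp = None
            cid = well.get("compound_id")
            if cid is not None and not pd.isna(cid) and registry is not None:
                comp = registry.get(cid)
            frac = myofibroblast_fraction(
                well["tgf_ng_ml"], comp, well.get("conc_nM", 0.0), dp, rng
            )

    H, W = shape
    channels = {ch: np.zeros((H, W), dtype=float) for ch in CHANNELS}
    cell_labels = np.zeros((H, W), dtype=np.int32)
    nucleus_labels = np.zeros((H, W), dtype=np.int32)

    max_a = math.sqrt(max(fib.cell_area_px2, myo.cell_area_px2) / math.pi) * 2.0
    margin = int(max_a) + 4
    if H - 2 * margin <= 0 or W - 2 * margin <= 0:
        raise ValueError("image too small for the largest cell template")

    g = max(1, math.ceil(math.sqrt(n_cells)))
    ys = np.linspace(margin, H - margin, g)
    xs = np.linspace(margin, W - margin, g)
    grid = [(y, x) for y in ys for x in xs]
    rng.shuffle(grid)
    spacing_y = (H - 2 * margin) / max(g - 1, 1)
    spacing_x = (W - 2 * margin) / max(g - 1, 1)

    labels = (rng.random(n_cells) < frac).astype(int)  # 1 = myofibroblast
    well_factor = float(rng.lognormal(0.0, WELL_BRIGHTNESS_SD)) if noise else 1.0
    truth_rows = []
    for i in range(n_cells):
        p = myo if labels[i] else fib
        brightness = well_factor * (
            float(rng.lognormal(0.0, p.brightness_sd)) if noise else 1.0
        )
        y0, x0 = grid[i]
        y0 += rng.uniform(-0.25, 0.25) * spacing_y
        x0 += rng.uniform(-0.25, 0.25) * spacing_x
        ecc = rng.uniform(*p.eccentricity)
        ratio = math.sqrt(1 - ecc**2)
        area = p.cell_area_px2 * (
            float(rng.lognormal(0.0, p.area_sd)) if noise else 1.0
        )
        area = float(np.clip(area, 40.0, 3.0 * p.cell_area_px2))
        a = math.sqrt(area / (math.pi * ratio))
        b = ratio * a
        theta = rng.uniform(0, math.pi)

        sz = 2 * int(math.ceil(a)) + 9
        y0 = float(np.clip(y0, sz // 2 + 1, H - sz // 2 - 2))
        x0 = float(np.clip(x0, sz // 2 + 1, W - sz // 2 - 2))
        mask = np.zeros((sz, sz), dtype=float)
        rr, cc = draw_ellipse(sz // 2, sz // 2, b, a, shape=mask.shape,
                              rotation=theta)
        mask[rr, cc] = 1.0

        nuc = np.zeros_like(mask)
        nuc_area = NUCLEUS_AREA_PX2 * (
            float(rng.lognormal(0.0, NUCLEUS_AREA_SD)) if noise else 1.0
        )
        nr_ax = min(math.sqrt(nuc_area / math.pi), 0.85 * b)
        nr, nc = draw_ellipse(sz // 2, sz // 2, max(nr_ax, 1.6),
                              max(1.15 * nr_ax, 1.6), shape=mask.shape,
                              rotation=theta)
        nuc[nr, nc] = 1.0

        dapi_jit = float(rng.lognormal(0.0, 0.25)) if noise else 1.0
        crops = {
            "dapi": ndi.gaussian_filter(nuc * NUCLEUS_INTENSITY * dapi_jit, 0.8),
            "wholecell": ndi.gaussian_filter(
                mask * WHOLECELL_INTENSITY + nuc * 800.0, 0.8
            ),
            "sma": _cell_crop(p, rng, "sma", mask, a, b, theta, brightness),
            "fn": _cell_crop(p, rng, "fn", mask, a, b, theta, brightness),
        }

        ri = int(round(y0)) - sz // 2
        ci = int(round(x0)) - sz // 2
        rs, cs = slice(ri, ri + sz), slice(ci, ci + sz)
        for ch in CHANNELS:
            channels[ch][rs, cs] += crops[ch]
        free = cell_labels[rs, cs] == 0
        cell_labels[rs, cs][free & (mask > 0)] = i + 1
        nucleus_labels[rs, cs][free & (nuc > 0)] = i + 1

        truth_rows.append(
            {
                "well": well_id, "cell_id": i + 1, "x": float(x0), "y": float(y0),
                "class": "myofibroblast" if labels[i] else "fibroblast",
            }
        )

    image = np.zeros((len(CHANNELS), H, W), dtype=np.uint16)
    cv = (fib.noise_cv + myo.noise_cv) / 2.0
    for k, ch in enumerate(CHANNELS):
        arr = channels[ch] + BACKGROUND_LEVEL
        if noise:
            sd = np.sqrt(READ_NOISE_SD**2 + (cv * arr) ** 2)
            arr = arr + rng.normal(0.0, 1.0, arr.shape) * sd
        image[k] = np.clip(arr, 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(
        truth_rows, columns=["well", "cell_id", "x", "y", "class"]
    )
    return SimulatedField(well_id, image, truth, cell_labels, nucleus_labels, frac)


def simulate_hca_plate(
    layout: PlateLayout,
    seed: int = 0,
    *,
    registry: CompoundRegistry | None = None,
    n_cells_per_well: int = 120,
    shape: tuple[int, int] = (384, 384),
    params: tuple[PhenotypeParams, PhenotypeParams] = (FIBROBLAST, MYOFIBROBLAST),
    dp: DifferentiationParams = DifferentiationParams(),
    wells: Iterable[str] | None = None,
    noise: bool = True,
) -> dict[str, SimulatedField]:
    """Render the selected wells of a plate (all wells by default).

    One master seed is split hierarchically so each well's field depends on
    (seed, well position) only, not on which other wells are rendered.
    """
    df = layout.wells
    if wells is not None:
        want = set(wells)
        df = df[df["well"].isin(want)]
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(layout.wells))
    seed_of = {w: s for w, s in zip(layout.wells["well"], children)}
    fields = {}
    for _, row in df.iterrows():
        fields[row["well"]] = simulate_cell_field(
            row, n_cells_per_well, params, seed_of[row["well"]],
            shape=shape, registry=registry, dp=dp, noise=noise,
        )
    return fields


# ---------------------------------------------------------------------------
# Impedance kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParams:
    """Shape parameters of the TGF-β1 impedance response.

    The response is a transient: a saturating rise (time constant
    ``rise_tau_h``) that declines exponentially after ``decline_onset_h``
    (~24 h). Amplitude is a Hill function of TGF-β1 dose. Relaxant
    compounds add an early dip peaking at ``nadir_tau_h`` hours.
    """

    rise_tau_h: float = 6.0
    decline_onset_h: float = 24.0
    decline_tau_h: float = 24.0
    amp_max: float = 0.5
    tgf_ec50_ng_ml: float = 0.5
    hill: float = 1.0
    nadir_tau_h: float = 2.5
    noise_sd: float = 0.01
    noise_rho: float = 0.8
    baseline_ci: float = 5.0

    def __post_init__(self) -> None:
        for name in ("rise_tau_h", "decline_tau_h", "nadir_tau_h", "baseline_ci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.amp_max < 0:
            raise ValueError("amp_max must be >= 0")


def pulse_shape(t, kp: KineticParams = KineticParams()):
    """Unit-amplitude transient: rise then post-onset exponential decline."""
    t = np.asarray(t, dtype=float)
    rise = 1.0 - np.exp(-np.maximum(t, 0.0) / kp.rise_tau_h)
    decline = np.where(
        t > kp.decline_onset_h,
        np.exp(-(t - kp.decline_onset_h) / kp.decline_tau_h),
        1.0,
    )
    return np.where(t < 0, 0.0, rise * decline)


def tgf_amplitude(dose_ng_ml: float, kp: KineticParams = KineticParams()) -> float:
    """Peak normalized cell-index amplitude as a Hill function of dose."""
    return kp.amp_max * _hill(dose_ng_ml, kp.tgf_ec50_ng_ml, kp.hill)


def relaxation_shape(t, kp: KineticParams = KineticParams()):
    """Unit-depth early relaxation dip with its minimum at ``nadir_tau_h``."""
    t = np.asarray(t, dtype=float)
    tn = np.maximum(t, 0.0) / kp.nadir_tau_h
    return np.where(t < 0, 0.0, tn * np.exp(1.0 - tn))


def simulate_impedance_trace(
    tgf_dose: float,
    compound: CompoundRecord | None = None,
    conc_nM: float = 0.0,
    times=None,
    kp: KineticParams = KineticParams(),
    seed: int | np.random.SeedSequence = 0,
    *,
    well: str = "A01",
):
    """Simulate a raw cell-index trace for one well.

    Model: CI(t) = baseline · (1 + A(dose)·f(conc)·pulse(t) − D·occ·dip(t))
    plus AR(1) noise, where f is the compound's remaining-response factor
    and D its relaxation depth. Returns an :class:`~fibroscreen.ipqa.ImpedanceTrace`
    in the ``raw`` state.
    """
    from .ipqa import ImpedanceTrace  # local to avoid cycle at import time

    if times is None:
        times = np.arange(0.0, 48.25, 0.25)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)

    amp = tgf_amplitude(tgf_dose, kp) * inhibition_remaining(conc_nM, compound)
    signal = 1.0 + amp * pulse_shape(times, kp)
    if compound is not None and compound.relax_depth > 0 and conc_nM > 0 and compound.ic50_nM:
        occ = conc_nM / (conc_nM + compound.ic50_nM)
        signal = signal - compound.relax_depth * occ * relaxation_shape(times, kp)

    noise = np.zeros_like(times)
    if kp.noise_sd > 0:
        eps = rng.normal(0.0, kp.noise_sd, times.size)
        for i in range(1, times.size):
            eps[i] += kp.noise_rho * eps[i - 1]
        noise = eps
    values = kp.baseline_ci * (signal + noise)
    return ImpedanceTrace(well, times, values, "raw", None)


# ---------------------------------------------------------------------------
# MRM peak areas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MsmsParams:
    """Generative model of the three-protein MRM panel.

    Tubulin peak area scales with cell number; marker/tubulin ratios follow
    1 + (F−1)·Hill(dose) with ~3-fold maximal induction and EC50 0.07
    (α-SMA) / 0.05 ng/ml (COL1A1), attenuated by compound occupancy.
    Noise is multiplicative log-normal per analyte.
    """

    tubulin_area_per_cell: float = 100.0
    fold_induction: float = 3.0
    ec50_acta_ng_ml: float = 0.07
    ec50_col1_ng_ml: float = 0.05
    hill: float = 1.0
    noise_cv: float = 0.10


def _ln_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv**2))


def simulate_msms_well(
    tgf_dose: float,
    compound: CompoundRecord | None = None,
    conc_nM: float = 0.0,
    n_cells: int = 4000,
    seed: int | np.random.SeedSequence = 0,
    mp: MsmsParams = MsmsParams(),
    *,
    well: str = "A01",
) -> PeptideQuant:
    """Simulate COL1A1/ACTA/TBA1A peak areas for one well."""
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    rng = np.random.default_rng(seed)
    sig = _ln_sigma(mp.noise_cv) if mp.noise_cv > 0 else 0.0

    def jitter() -> float:
        return float(rng.lognormal(0.0, sig)) if sig > 0 else 1.0

    remaining = inhibition_remaining(conc_nM, compound)
    tub = mp.tubulin_area_per_cell * n_cells * jitter()
    F = mp.fold_induction
    r_acta = 1.0 + (F - 1.0) * _hill(tgf_dose, mp.ec50_acta_ng_ml, mp.hill) * remaining
    r_col1 = 1.0 + (F - 1.0) * _hill(tgf_dose, mp.ec50_col1_ng_ml, mp.hill) * remaining
    return PeptideQuant(
        well=well,
        area_col1a1=r_col1 * tub * jitter(),
        area_acta=r_acta * tub * jitter(),
        area_tba1a=tub,
    )


def simulate_msms_reversal_well(
    compound: CompoundRecord | None,
    conc_nM: float,
    n_cells: int = 4000,
    seed: int | np.random.SeedSequence = 0,
    mp: MsmsParams = MsmsParams(),
    dp: DifferentiationParams = DifferentiationParams(),
    *,
    well: str = "A01",
) -> PeptideQuant:
    """Peak areas at the reversal-mode endpoint (96 h): marker induction is
    proportional to the persisting myofibroblast fraction."""
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    rng = np.random.default_rng(seed)
    sig = _ln_sigma(mp.noise_cv) if mp.noise_cv > 0 else 0.0

    def jitter() -> float:
        return float(rng.lognormal(0.0, sig)) if sig > 0 else 1.0

    frac = reversal_myo_fraction(compound, conc_nM, dp)
    rel = frac / dp.f_max if dp.f_max > 0 else 0.0
    tub = mp.tubulin_area_per_cell * n_cells * jitter()
    r = 1.0 + (mp.fold_induction - 1.0) * rel
    return PeptideQuant(
        well=well,
        area_col1a1=r * tub * jitter(),
        area_acta=r * tub * jitter(),
        area_tba1a=tub,
    )


# ---------------------------------------------------------------------------
# Well-level screening readouts (no image rendering)
# ---------------------------------------------------------------------------


def simulate_screen_readouts(
    registry: CompoundRegistry,
    conc_nM: float = 10000.0,
    seed: int = 0,
    *,
    n_cells: int = 400,
    n_control_wells: int = 16,
    tgf_dose: float = 5.0,
    viability_noise_sd: float = 2.0,
    dp: DifferentiationParams = DifferentiationParams(),
) -> pd.DataFrame:
    """Single-concentration primary screen at the well-readout level.

    Each compound well draws its classified cell count from a binomial at
    the dose-rule myofibroblast fraction; control wells anchor the percent
    effect. Toxic compounds lose cells and viability signal according to
    their toxicity EC50. Returns one row per compound:
    ``compound_id, percent_inhibition, viability_reduction_pct``.
    """
    rng = np.random.default_rng(seed)

    def well_fraction(f: float, n: int) -> float:
        n = max(int(n), 1)
        return rng.binomial(n, min(max(f, 0.0), 1.0)) / n

    f_neg = [
        well_fraction(myofibroblast_fraction(tgf_dose, None, 0, dp, rng), n_cells)
        for _ in range(n_control_wells)
    ]
    f_pos = [
        well_fraction(myofibroblast_fraction(0.0, None, 0, dp, rng), n_cells)
        for _ in range(n_control_wells)
    ]
    mu_neg, mu_pos = float(np.mean(f_neg)), float(np.mean(f_pos))
    if mu_neg == mu_pos:
        raise ValueError("degenerate synthetic controls")

    rows = []
    for rec in registry:
        tox_red = 0.0
        if rec.toxic and rec.tox_ec50_nM:
            tox_red = conc_nM / (conc_nM + rec.tox_ec50_nM)
        n_surv = max(int(round(n_cells * (1.0 - tox_red))), 1)
        f = myofibroblast_fraction(tgf_dose, rec, conc_nM, dp, rng)
        f_obs = well_fraction(f, n_surv)
        inhib = 100.0 * (mu_neg - f_obs) / (mu_neg - mu_pos)
        viab = 100.0 * tox_red + rng.normal(0.0, viability_noise_sd)
        rows.append(
            {
                "compound_id": rec.compound_id,
                "percent_inhibition": inhib,
                "viability_reduction_pct": float(np.clip(viab, 0.0, 100.0)),
            }
        )
    return pd.DataFrame(rows)


def simulate_confirmation_series(
    compound: CompoundRecord,
    concs_nM,
    seed: int = 0,
    *,
    n_cells: int = 400,
    tgf_dose: float = 5.0,
    dp: DifferentiationParams = DifferentiationParams(),
) -> pd.DataFrame:
    """Concentration–response percent inhibition for one compound."""
    rng = np.random.default_rng(seed)
    f_neg = myofibroblast_fraction(tgf_dose, None, 0, dp)
    f_pos = myofibroblast_fraction(0.0, None, 0, dp)
    rows = []
    for c in np.asarray(concs_nM, dtype=float):
        f = myofibroblast_fraction(tgf_dose, compound, c, dp, rng)
        f_obs = rng.binomial(n_cells, min(max(f, 0.0), 1.0)) / n_cells
        rows.append(
            {
                "conc_nM": float(c),
                "percent_inhibition": 100.0 * (f_neg - f_obs) / (f_neg - f_pos),
            }
        )
    return pd.DataFrame(rows)
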