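"""Synthetic-data generation.

Emulates the statistical structure of a two-condition label-free
shotgun-proteomics experiment — two acclimation temperatures, five
biological replicates each — so that every downstream stage (quantitation,
assembly, differential testing, ordination, enrichment) is testable without
any external data. Ground truth (which proteins are truly up/down and by
how much) is emitted alongside for parameter-recovery tests.

The intensity model is multiplicative: per protein a log-normal base
abundance, a condition effect of 10**log10_fc on the elevated condition for
truly regulated proteins, and mean-1 log-normal replicate noise with a
stated coefficient of variation. Values below the noise floor, plus an
independent missing-completely-at-random mask (or optionally a
low-abundance-biased mask), become missing. A spiked reference peptide row
is always complete and carries no condition effect. Chromatogram fixtures
are sums of Gaussian peaks with optional white noise and per-replicate RT
shifts; their exact areas (height * sigma * sqrt(2*pi)) are returned for
oracle tests.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemble import CONDITION_CONTROL, CONDITION_ELEVATED, QuantMatrix
from .quant import Chromatogram

__all__ = [
    "SynthError",
    "SynthConfig",
    "generate_intensity_matrix",
    "generate_chromatogram_set",
    "generate_annotation_map",
]


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the emulated experiment: 1532 quantified proteins, five
    replicates per condition, roughly 2% of proteins truly up and 2% truly
    down, with log10 fold changes drawn uniformly from 0.2-2.2 (1.6-fold up
    to 160-fold) to span the range such experiments report. ``cv`` is the
    within-condition coefficient of variation of raw intensities (a free
    parameter; 0.2 is a typical label-free replicate CV). ``log10_fc_up`` /
    ``log10_fc_down`` may be a single value or a (low, high) range.
    """

    n_proteins: int = 1532
    peptides_per_protein: int = 2
    n_replicates: int = 5
    frac_up: float = 31 / 1532
    frac_down: float = 31 / 1532
    log10_fc_up: float | tuple[float, float] = (0.2, 2.2)
    log10_fc_down: float | tuple[float, float] = (0.2, 2.2)
    cv: float = 0.2
    missing_rate: float = 0.02
    missing_mode: str = "mcar"  # or "intensity" (low-abundance biased)
    noise_floor: float = 1000.0
    base_log10_mean: float = 5.5
    base_log10_sd: float = 0.7
    spike_label: str = "DRVYHPF"
    spike_intensity: float = 1.0e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise SynthError("n_replicates must be >= 2")
        if self.n_proteins < 1 or self.peptides_per_protein < 1:
            raise SynthError("n_proteins and peptides_per_protein must be >= 1")
        for name in ("frac_up", "frac_down", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthError(f"{name} must be in [0, 1], got {v}")
        if self.frac_up + self.frac_down > 1.0:
            raise SynthError("frac_up + frac_down must be <= 1")
        if self.cv < 0:
            raise SynthError("cv must be non-negative")
        if self.missing_mode not in ("mcar", "intensity"):
            raise SynthError(f"unknown missing_mode {self.missing_mode!r}")


def _sample_ids(n: int) -> tuple[list[str], list[str]]:
    letters = string.ascii_uppercase
    tags = [letters[i] if i < 26 else f"{letters[i // 26 - 1]}{letters[i % 26]}" for i in range(n)]
    return [f"R18_{t}" for t in tags], [f"R22_{t}" for t in tags]


def _draw_effects(rng: np.random.Generator, spec, n: int) -> np.ndarray:
    if np.isscalar(spec):
        return np.full(n, float(spec))
    lo, hi = spec
    return rng.uniform(float(lo), float(hi), size=n)


def generate_intensity_matrix(cfg: SynthConfig) -> tuple[QuantMatrix, pd.DataFrame]:
    """Generate a protein x sample intensity matrix plus ground truth.

    Returns the raw-scale :class:`~lfquant.assemble.QuantMatrix` (spike row
    included, labeled by ``cfg.spike_label``) and a ground-truth table with
    columns ``protein``, ``true_class`` in {up, down, null}, ``true_log10_fc``
    and ``true_mean`` (the base raw intensity). Deterministic under a fixed
    seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    proteins = [f"P{i + 1:05d}" for i in range(n)]

    n_up = round(cfg.frac_up * n)
    n_down = round(cfg.frac_down * n)
    classes = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_up]] = "up"
    classes[order[n_up : n_up + n_down]] = "down"

    log10_fc = np.zeros(n)
    log10_fc[classes == "up"] = _draw_effects(rng, cfg.log10_fc_up, n_up)
    log10_fc[classes == "down"] = -_draw_effects(rng, cfg.log10_fc_down, n_down)

    base = 10.0 ** rng.normal(cfg.base_log10_mean, cfg.base_log10_sd, size=n)

    ctrl_ids, elev_ids = _sample_ids(cfg.n_replicates)
    samples = ctrl_ids + elev_ids
    effect = np.column_stack(
        [np.ones((n, cfg.n_replicates)), np.tile(10.0 ** log10_fc[:, None], (1, cfg.n_replicates))]
    )

    # mean-1 log-normal noise: sd/mean == cv exactly
    sigma = np.sqrt(np.log1p(cfg.cv**2))
    noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=(n + 1, 2 * cfg.n_replicates)))

    values = base[:, None] * effect * noise[:n]
    spike_row = cfg.spike_intensity * noise[n]

    matrix = np.vstack([values, spike_row])

    # missingness: never the spike row, never below-floor clamping — below
    # floor IS missing, matching how the noise floor is applied downstream
    if cfg.missing_mode == "mcar":
        p_miss = np.full(values.shape, cfg.missing_rate)
    else:
        # low-abundance biased: logistic in log10 intensity around the
        # 20th percentile, scaled so the average rate ~ missing_rate
        lv = np.log10(values)
        pivot = np.quantile(lv, 0.2)
        w = 1.0 / (1.0 + np.exp(2.0 * (lv - pivot)))
        p_miss = np.clip(cfg.missing_rate * w / max(w.mean(), 1e-12), 0.0, 1.0)
    miss = rng.random(values.shape) < p_miss
    matrix[:n][miss] = np.nan
    matrix[matrix < cfg.noise_floor] = np.nan
    if np.isnan(matrix[n]).any():
        raise SynthError(
            "spike intensity fell below the noise floor; raise spike_intensity or lower cv"
        )

    data = pd.DataFrame(matrix, index=proteins + [cfg.spike_label], columns=samples)
    data.index.name = "protein"
    conditions = pd.Series(
        [CONDITION_CONTROL] * cfg.n_replicates + [CONDITION_ELEVATED] * cfg.n_replicates,
        index=samples,
    )
    truth = pd.DataFrame(
        {
            "protein": proteins,
            "true_class": classes,
            "true_log10_fc": log10_fc,
            "true_mean": base,
        }
    )
    return QuantMatrix(data, conditions), truth


def generate_chromatogram_set(
    cfg: SynthConfig,
    peak_spec: list[tuple[float, float, float]],
    rt_range: tuple[float, float] = (0.0, 600.0),
    dt: float = 0.5,
    noise_sigma: float = 0.0,
    shifts: np.ndarray | list[float] | None = None,
    peptide: str = "PEPTIDE",
) -> tuple[dict[str, Chromatogram], list[float]]:
    """Simulate replicate chromatogram traces for one peptide.

    ``peak_spec`` is a list of ``(rt_apex, width_sigma, height)`` Gaussians
    (overlapping apexes allowed; negative heights rejected). Each replicate
    trace is the peak sum plus white noise of ``noise_sigma`` (negative
    excursions clipped at 0) and a per-replicate additive RT shift for
    alignment testing. Returns ``{replicate_id: Chromatogram}`` together
    with the closed-form true areas ``height * sigma * sqrt(2*pi)``.
    """
    lo, hi = rt_range
    if hi <= lo or dt <= 0:
        raise SynthError("invalid rt_range or dt")
    for apex, width, height in peak_spec:
        if not lo <= apex <= hi:
            raise SynthError(f"peak apex {apex} outside RT range {rt_range}")
        if width <= 0:
            raise SynthError("peak width_sigma must be positive")
        if height < 0:
            raise SynthError("peak height must be non-negative")
    n_rep = cfg.n_replicates
    if shifts is None:
        shifts = np.zeros(n_rep)
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (n_rep,):
        raise SynthError(f"shifts must have length n_replicates={n_rep}")

    rng = np.random.default_rng(cfg.seed)
    rt = np.arange(lo, hi + 0.5 * dt, dt)
    out: dict[str, Chromatogram] = {}
    for r in range(n_rep):
        rep_id = f"rep{r + 1}"
        y = np.zeros_like(rt)
        for apex, width, height in peak_spec:
            y += height * np.exp(-0.5 * ((rt - (apex + shifts[r])) / width) ** 2)
        if noise_sigma > 0:
            y = np.clip(y + rng.normal(0.0, noise_sigma, size=rt.shape), 0.0, None)
        out[rep_id] = Chromatogram(rt, y, peptide=peptide, replicate=rep_id)
    true_areas = [height * width * np.sqrt(2.0 * np.pi) for _, width, height in peak_spec]
    return out, true_areas


def generate_annotation_map(
    proteins: list[str],
    n_categories: int = 12,
    frac_annotated: float = 0.87,
    terms_per_protein: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random flat annotation map for enrichment-stage testing.

    A fraction of proteins stays unannotated, as real ortholog/GO mapping
    leaves a tail of unmapped identifiers. Categories are drawn with
    log-uniform sizes so a few large and many small terms exist.
    """
    rng = np.random.default_rng(seed)
    cats = [f"GO:{i + 1:07d}" for i in range(n_categories)]
    weights = 10.0 ** rng.uniform(-1.5, 0.0, size=n_categories)
    weights /= weights.sum()
    ann: dict[str, set[str]] = {}
    lo, hi = terms_per_protein
    for p in proteins:
        if rng.random() > frac_annotated:
            continue
        k = int(rng.integers(lo, hi + 1))
        ann[p] = set(rng.choice(cats, size=k, replace=False, p=weights))
    return ann
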