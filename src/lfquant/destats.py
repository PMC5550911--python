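"""Differential-expression decision procedure.

Per protein, a two-sample Student's t-test and an exact Mann-Whitney U-test
are both computed on log10 intensities; Benjamini-Hochberg Q-values are
attached; a fold-change cutoff expressed in "decibels" (10*log10 of the
elevated/control ratio) is either fixed or derived from an anchor protein —
the protein with the smallest fold change among those with Q below a
threshold; and a protein is called differentially expressed only when both
p-values fall below alpha AND its fold change clears the cutoff. The dual
test guards against both non-normality (t) and low power at n=5 (U); the
anchor-derived cutoff ties the fold-change criterion to a protein that
survives a stringent false-discovery test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assemble import QuantMatrix

__all__ = [
    "DEError",
    "DEConfig",
    "test_protein",
    "bh_qvalues",
    "fold_change",
    "linear_thresholds",
    "derive_cutoff",
    "call_de",
]

log = logging.getLogger(__name__)


class DEError(ValueError):
    pass


@dataclass(frozen=True)
class DEConfig:
    """Decision-rule configuration.

    ``cutoff_db`` of ``None`` derives the cutoff from the anchor protein;
    a number fixes it (2.0 dB corresponds to the 1.58x / 0.63x linear
    thresholds). ``fold_change_basis`` chooses between the ratio of
    raw-scale group means ("arithmetic_means") and the back-transformed
    difference of log10 means ("geometric_means"). ``q_basis`` selects
    which p-value family feeds the BH correction. ``truncate_cutoff``
    truncates the derived cutoff to one decimal (10*log10 1.6 = 2.04 ->
    2.0); exact mode keeps it untruncated.
    """

    alpha: float = 0.05
    anchor_q_max: float = 0.05
    cutoff_db: float | None = None
    fold_change_basis: str = "arithmetic_means"
    q_basis: str = "t"  # or "u"
    equal_var: bool = True  # classic Student's t; False = Welch
    truncate_cutoff: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DEError("alpha must be in (0, 1)")
        if not 0 < self.anchor_q_max < 1:
            raise DEError("anchor_q_max must be in (0, 1)")
        if self.cutoff_db is not None and self.cutoff_db <= 0:
            raise DEError("cutoff_db must be positive")
        if self.fold_change_basis not in ("arithmetic_means", "geometric_means"):
            raise DEError(f"unknown fold_change_basis {self.fold_change_basis!r}")
        if self.q_basis not in ("t", "u"):
            raise DEError(f"unknown q_basis {self.q_basis!r}")


# ---------------------------------------------------------------------------
# per-protein tests
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 8


def _p_t(control: np.ndarray, elevated: np.ndarray, equal_var: bool) -> float:
    if np.var(control) == 0 and np.var(elevated) == 0:
        # degenerate: no within-group variation at all
        if np.mean(control) == np.mean(elevated):
            return 1.0
        log.warning("constant unequal groups; t-test p set to 0")
        return 0.0
    return float(stats.ttest_ind(control, elevated, equal_var=equal_var).pvalue)


def _p_u(control: np.ndarray, elevated: np.ndarray) -> float:
    n, m = len(control), len(elevated)
    u = float(stats.mannwhitneyu(control, elevated, method="asymptotic").statistic)
    if u == 0.5 * n * m:
        # dead-center statistic (e.g. identical groups): two-sided p is 1
        return 1.0
    pooled = np.concatenate([control, elevated])
    ties = len(np.unique(pooled)) < len(pooled)
    if n <= _EXACT_MAX_N and m <= _EXACT_MAX_N and not ties:
        method = "exact"
    else:
        # normal approximation; scipy applies the tie correction
        method = "asymptotic"
    return float(stats.mannwhitneyu(control, elevated, method=method).pvalue)


def test_protein(
    control: np.ndarray, elevated: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided t-test and Mann-Whitney U p-values for one protein.

    The U-test is exact (full enumeration of labelings) for group sizes up
    to 8 without ties, and a tie-corrected normal approximation otherwise.
    Values are expected on the log10 scale (the U-test is rank-based, so
    the transform does not affect it).
    """
    control = np.asarray(control, dtype=float)
    elevated = np.asarray(elevated, dtype=float)
    if len(control) < 2 or len(elevated) < 2:
        raise DEError("need >= 2 observations per group")
    return _p_t(control, elevated, equal_var), _p_u(control, elevated)


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DEError("p must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DEError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# fold changes and the anchor-derived cutoff
# ---------------------------------------------------------------------------


def fold_change(
    control: np.ndarray, elevated: np.ndarray, basis: str = "arithmetic_means"
) -> tuple[float, float]:
    """Elevated/control fold change and its decibel score 10*log10(FC).

    ``control`` and ``elevated`` are raw-scale (positive) intensities.
    Arithmetic basis: ratio of the raw group means. Geometric basis:
    back-transformed difference of log10 means.
    """
    control = np.asarray(control, dtype=float)
    elevated = np.asarray(elevated, dtype=float)
    if np.any(control <= 0) or np.any(elevated <= 0):
        raise DEError("fold_change requires positive raw-scale values")
    if basis == "arithmetic_means":
        fc = float(np.mean(elevated) / np.mean(control))
    elif basis == "geometric_means":
        fc = float(10.0 ** (np.mean(np.log10(elevated)) - np.mean(np.log10(control))))
    else:
        raise DEError(f"unknown fold-change basis {basis!r}")
    return fc, 10.0 * np.log10(fc)


def linear_thresholds(cutoff_db: float) -> tuple[float, float]:
    """Linear up/down fold-change thresholds for a decibel cutoff.

    2.0 dB -> (1.58, 0.63): up-regulated means FC > 10**(cutoff/10),
    down-regulated FC < 10**(-cutoff/10).
    """
    if cutoff_db <= 0:
        raise DEError("cutoff_db must be positive")
    return 10.0 ** (cutoff_db / 10.0), 10.0 ** (-cutoff_db / 10.0)


def derive_cutoff(
    results: pd.DataFrame, anchor_q_max: float = 0.05, truncate: bool = True
) -> tuple[float, str]:
    """Anchor-derived fold-change cutoff.

    The anchor is the protein with the smallest (symmetrized, max(FC, 1/FC))
    fold change among those with Q below ``anchor_q_max``; the cutoff is
    |10*log10(FC_anchor)|, truncated to one decimal unless ``truncate`` is
    False. ``results`` needs ``protein``, ``fold_change`` and ``q`` columns.
    Raises when no protein passes the Q threshold — fix ``cutoff_db``
    explicitly in that case.
    """
    sel = results[results["q"] < anchor_q_max]
    if sel.empty:
        raise DEError(
            f"no protein has Q < {anchor_q_max}; no anchor available — "
            "set a fixed cutoff_db instead"
        )
    sym = np.maximum(sel["fold_change"], 1.0 / sel["fold_change"])
    # deterministic tie-break on protein id
    sel = sel.assign(_sym=sym).sort_values(["_sym", "protein"], kind="mergesort")
    anchor = sel.iloc[0]
    db = abs(10.0 * np.log10(anchor["fold_change"]))
    if truncate:
        db = np.floor(db * 10.0) / 10.0
    if db <= 0:
        raise DEError(f"anchor {anchor['protein']!r} has zero fold change; cannot derive cutoff")
    return float(db), str(anchor["protein"])


# ---------------------------------------------------------------------------
# the combined call
# ---------------------------------------------------------------------------


def _group_values(matrix: QuantMatrix) -> tuple[np.ndarray, np.ndarray]:
    labels = matrix.condition_labels
    if len(labels) != 2:
        raise DEError(f"exactly two conditions required, got {labels}")
    ctrl = matrix.data[matrix.samples_for(labels[0])].to_numpy(dtype=float)
    elev = matrix.data[matrix.samples_for(labels[1])].to_numpy(dtype=float)
    return ctrl, elev


def call_de(matrix: QuantMatrix, cfg: DEConfig = DEConfig(), exclude: tuple[str, ...] = ()) -> tuple[pd.DataFrame, dict]:
    """Run the full decision procedure on a log10 matrix.

    Returns the per-protein result table (``protein``, raw-scale group
    means, ``fold_change``, ``score_db``, ``p_t``, ``p_u``, ``q``, ``call``)
    and a metadata dict (cutoff in dB, linear thresholds, anchor id,
    config). ``exclude`` lists rows — typically the spike — dropped before
    testing. Tests run on the available observations of each group; rows
    where a group has fewer than two observations are called ``ns`` with
    NaN p-values.
    """
    if not matrix.log10:
        raise DEError("call_de expects a log10-transformed matrix")
    m = matrix
    if exclude:
        keep = [p for p in m.data.index if p not in set(exclude)]
        m = QuantMatrix(m.data.loc[keep], m.conditions.copy(), m.log10)
    ctrl_log, elev_log = _group_values(m)
    proteins = list(m.data.index)
    n = len(proteins)

    p_t = np.full(n, np.nan)
    p_u = np.full(n, np.nan)
    fc = np.full(n, np.nan)
    score = np.full(n, np.nan)
    mean_c = np.full(n, np.nan)
    mean_e = np.full(n, np.nan)

    complete = ~np.isnan(ctrl_log).any(axis=1) & ~np.isnan(elev_log).any(axis=1)

    # vectorized path for fully observed rows (the common case)
    idx = np.flatnonzero(complete)
    if idx.size:
        a, b = ctrl_log[idx], elev_log[idx]
        tt = stats.ttest_ind(a, b, axis=1, equal_var=cfg.equal_var)
        p_t[idx] = tt.pvalue
        nm = a.shape[1] * b.shape[1]
        has_tie = np.array(
            [len(np.unique(np.concatenate([a[i], b[i]]))) < a.shape[1] + b.shape[1] for i in range(len(idx))]
        )
        small = a.shape[1] <= _EXACT_MAX_N and b.shape[1] <= _EXACT_MAX_N
        if small and (~has_tie).any():
            j = np.flatnonzero(~has_tie)
            mw = stats.mannwhitneyu(a[j], b[j], axis=1, method="exact")
            p_u[idx[j]] = mw.pvalue
            u_stat = np.asarray(mw.statistic, dtype=float)
            p_u[idx[j][u_stat == 0.5 * nm]] = 1.0
        for j in np.flatnonzero(has_tie) if small else range(len(idx)):
            p_u[idx[j]] = _p_u(a[j], b[j])
        # degenerate zero-variance rows (possible at cv -> 0)
        degen = (np.var(a, axis=1) == 0) & (np.var(b, axis=1) == 0)
        for j in np.flatnonzero(degen):
            p_t[idx[j]] = _p_t(a[j], b[j], cfg.equal_var)

    for i in np.flatnonzero(~complete):
        c = ctrl_log[i][~np.isnan(ctrl_log[i])]
        e = elev_log[i][~np.isnan(elev_log[i])]
        if len(c) < 2 or len(e) < 2:
            log.warning("protein %s has <2 observations in a group; not testable", proteins[i])
            continue
        p_t[i], p_u[i] = test_protein(c, e, cfg.equal_var)

    for i in range(n):
        c = 10.0 ** ctrl_log[i][~np.isnan(ctrl_log[i])]
        e = 10.0 ** elev_log[i][~np.isnan(elev_log[i])]
        if len(c) == 0 or len(e) == 0:
            continue
        mean_c[i], mean_e[i] = float(np.mean(c)), float(np.mean(e))
        if len(c) >= 1 and len(e) >= 1:
            fc[i], score[i] = fold_change(c, e, cfg.fold_change_basis)

    p_for_q = p_t if cfg.q_basis == "t" else p_u
    q = np.full(n, np.nan)
    ok = ~np.isnan(p_for_q)
    if ok.any():
        q[ok] = bh_qvalues(p_for_q[ok])

    results = pd.DataFrame(
        {
            "protein": proteins,
            "mean_control": mean_c,
            "mean_elevated": mean_e,
            "fold_change": fc,
            "score_db": score,
            "p_t": p_t,
            "p_u": p_u,
            "q": q,
        }
    )

    if cfg.cutoff_db is not None:
        cutoff_db, anchor = float(cfg.cutoff_db), None
    else:
        cutoff_db, anchor = derive_cutoff(results, cfg.anchor_q_max, cfg.truncate_cutoff)
    up_thr, down_thr = linear_thresholds(cutoff_db)

    sig = (results["p_t"] < cfg.alpha) & (results["p_u"] < cfg.alpha)
    call = np.where(
        sig & (results["score_db"] > cutoff_db),
        "up",
        np.where(sig & (results["score_db"] < -cutoff_db), "down", "ns"),
    )
    call[results["p_t"].isna() | results["p_u"].isna() | results["score_db"].isna()] = "ns"
    results["call"] = call

    meta = {
        "cutoff_db": cutoff_db,
        "threshold_up": up_thr,
        "threshold_down": down_thr,
        "anchor": anchor,
        "alpha": cfg.alpha,
        "fold_change_basis": cfg.fold_change_basis,
        "q_basis": cfg.q_basis,
        "n_up": int((results["call"] == "up").sum()),
        "n_down": int((results["call"] == "down").sum()),
        "n_ns": int((results["call"] == "ns").sum()),
    }
    return results, meta
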