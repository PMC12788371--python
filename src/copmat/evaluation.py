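"""Leave-one-subject-out evaluation, metrics, and repeated-measures ANOVA.

Metrics per direction (ML, AP):

    RMSE  = sqrt( sum_i (y_i - yhat_i)^2 / n )                      [mm]
    NRMSE = RMSE / (y_max - y_min) * 100                            [%]
    R^2   = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2

with the NRMSE range taken from the ground truth of the evaluated
vector (per validation subject per stratum by default).  Model and
input-condition effects on per-subject RMSE are tested with a two-way
repeated-measures ANOVA (within-subject factors Model x Input
Condition, subject as the blocking factor), with Greenhouse-Geisser
corrected p-values reported alongside the uncorrected ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STATIC_PROTOCOLS = ("one_leg", "tandem")
DYNAMIC_PROTOCOLS = ("squat", "walk_in_place")
DIRECTIONS = ("ML", "AP")
STRATA = ("overall", "static", "dynamic")


@dataclass(frozen=True)
class Metrics:
    """RMSE in mm, NRMSE in percent, R-squared (dimensionless).

    ``nrmse`` and ``r2`` are None when the ground truth is constant
    (zero range / zero variance) — typed undefined rather than NaN.
    """

    rmse: float
    nrmse: float | None
    r2: float | None


def compute_metrics(y, y_hat, nrmse_range: float | None = None) -> Metrics:
    """Per-direction error metrics of one prediction vector.

    ``nrmse_range`` overrides the normalization range (e.g. the pooled
    ground-truth range over all validation data instead of this
    vector's own range).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    n = len(y)
    if n < 2:
        raise ValueError("need at least two samples")
    sq = np.sum((y - y_hat) ** 2)
    rmse = float(np.sqrt(sq / n))
    rng = y.max() - y.min() if nrmse_range is None else float(nrmse_range)
    nrmse = float(rmse / rng * 100.0) if rng > 0 else None
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(1.0 - sq / ss_tot) if ss_tot > 0 else None
    return Metrics(rmse=rmse, nrmse=nrmse, r2=r2)


def loocv_split(subject_ids) -> list[tuple[list, list]]:
    """Leave-one-subject-out folds: each subject validates exactly once."""
    ids = list(subject_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate subject ids")
    if len(ids) < 2:
        raise ValueError("LOOCV needs at least two subjects")
    return [([s for s in ids if s != held], [held]) for held in ids]


@dataclass
class FoldResult:
    """Evaluation of one held-out subject for one model/condition."""

    held_out_subject: str
    model_name: str
    condition: str  # "WA" | "OT"
    # protocol -> (y (n,2), y_hat (n,2)) in [ML, AP] mm
    vectors: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)  # (stratum, direction) -> Metrics

    def compute(self) -> "FoldResult":
        groups = {
            "overall": list(self.vectors),
            "static": [p for p in self.vectors if p in STATIC_PROTOCOLS],
            "dynamic": [p for p in self.vectors if p in DYNAMIC_PROTOCOLS],
        }
        for stratum, protos in groups.items():
            if not protos:
                continue  # stratum absent for this fold, not zero
            y = np.concatenate([self.vectors[p][0] for p in protos])
            y_hat = np.concatenate([self.vectors[p][1] for p in protos])
            for d, name in enumerate(DIRECTIONS):
                self.metrics[(stratum, name)] = compute_metrics(y[:, d], y_hat[:, d])
        return self


def stratify_and_summarize(fold_results: list[FoldResult]) -> pd.DataFrame:
    """Mean (SD) of each metric across folds, per model/condition/stratum.

    Returns a tidy table with one row per (model, condition, stratum,
    direction, metric); the directional gap ML - AP of each metric mean
    is recoverable by pivoting.  Folds missing a stratum are simply
    absent from that cell.
    """
    rows = []
    for fr in fold_results:
        for (stratum, direction), m in fr.metrics.items():
            for metric in ("rmse", "nrmse", "r2"):
                v = getattr(m, metric)
                if v is None:
                    continue
                rows.append(dict(model=fr.model_name, condition=fr.condition,
                                 stratum=stratum, direction=direction,
                                 metric=metric, subject=fr.held_out_subject,
                                 value=v))
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no fold results to summarize")
    out = (df.groupby(["model", "condition", "stratum", "direction", "metric"])
           ["value"].agg(["mean", "std", "count"]).reset_index()
           .rename(columns={"std": "sd", "count": "n_folds"}))
    return out


def directional_gap(summary: pd.DataFrame, metric: str = "rmse",
                    stratum: str = "overall") -> pd.DataFrame:
    """ML minus AP mean metric per (model, condition)."""
    sub = summary[(summary.metric == metric) & (summary.stratum == stratum)]
    piv = sub.pivot_table(index=["model", "condition"], columns="direction",
                          values="mean")
    piv["gap"] = piv["ML"] - piv["AP"]
    return piv.reset_index()


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA

def _gg_epsilon(cells: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for the effect with contrast basis C.

    ``cells`` is (n_subjects, k) scores; C has shape (df, k) with
    orthonormal rows spanning the effect's contrast space.
    """
    S = np.cov(cells, rowvar=False)
    M = C @ S @ C.T
    tr = np.trace(M)
    denom = M.shape[0] * np.trace(M @ M)
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(tr**2 / denom, 1.0 / M.shape[0])))


def _helmert(k: int) -> np.ndarray:
    """(k-1, k) orthonormal contrast rows."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


def rm_anova_2way(
    data,
    subject_col: str = "subject",
    factor_a: str = "model",
    factor_b: str = "condition",
    value_col: str = "rmse",
) -> pd.DataFrame:
    """Two-way fully within-subject ANOVA on a balanced complete table.

    ``data`` is a tidy DataFrame (subject, model, condition, value) or
    an (n_subjects, a, b) array.  For each effect (A, B, A x B):
    ``F = MS_effect / MS_(effect x subject)`` with the subject as the
    blocking factor; p from the F distribution, plus Greenhouse-Geisser
    corrected p.  Missing cells raise (no imputation).
    """
    if isinstance(data, pd.DataFrame):
        piv = data.pivot_table(index=subject_col, columns=[factor_a, factor_b],
                               values=value_col, aggfunc="count")
        if piv.isna().any().any() or (piv != 1).any().any():
            raise ValueError("design must be balanced and complete (one value per cell)")
        wide = data.pivot_table(index=subject_col, columns=[factor_a, factor_b],
                                values=value_col)
        a_levels = wide.columns.levels[0]
        b_levels = wide.columns.levels[1]
        Y = wide.values.reshape(len(wide), len(a_levels), len(b_levels))
    else:
        Y = np.asarray(data, dtype=float)
        if Y.ndim != 3:
            raise ValueError("array input must be (subjects, a, b)")
        if np.isnan(Y).any():
            raise ValueError("missing cells are not allowed")
    s, a, b = Y.shape
    if s < 3:
        raise ValueError("need at least three subjects")

    gm = Y.mean()
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_s = Y.mean(axis=(1, 2))
    m_ab = Y.mean(axis=0)
    m_as = Y.mean(axis=2)
    m_bs = Y.mean(axis=1)

    ss_a = s * b * np.sum((m_a - gm) ** 2)
    ss_b = s * a * np.sum((m_b - gm) ** 2)
    ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + gm) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + gm) ** 2)
    ss_abs = np.sum(
        (Y - m_ab[None] - m_as[:, :, None] - m_bs[:, None, :]
         + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None] - gm) ** 2
    )

    effects = [
        ("A", ss_a, a - 1, ss_as, (a - 1) * (s - 1)),
        ("B", ss_b, b - 1, ss_bs, (b - 1) * (s - 1)),
        ("AxB", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (s - 1)),
    ]
    # contrast bases for GG epsilon, applied to the (n, a*b) cell matrix
    Ha, Hb = _helmert(a), _helmert(b)
    ones_a = np.ones((1, a)) / np.sqrt(a)
    ones_b = np.ones((1, b)) / np.sqrt(b)
    contrast = {
        "A": np.kron(Ha, ones_b),
        "B": np.kron(ones_a, Hb),
        "AxB": np.kron(Ha, Hb),
    }
    cells = Y.reshape(s, a * b)
    ss_scale = max(float(np.sum((Y - gm) ** 2)), 1.0)
    rows = []
    for name, ss_eff, df1, ss_err, df2 in effects:
        # sums of squares below float roundoff of the data are exact ties
        if ss_eff <= 1e-12 * ss_scale:
            ss_eff = 0.0
        if ss_err <= 1e-12 * ss_scale:
            ss_err = 0.0
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        if ms_err > 0:
            F = ms_eff / ms_err
        else:
            # degenerate: no residual variation; a zero effect is F = 0
            F = 0.0 if ms_eff == 0.0 else np.inf
        p = float(stats.f.sf(F, df1, df2))
        eps = _gg_epsilon(cells, contrast[name])
        p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps))
        rows.append(dict(effect=name, SS=ss_eff, df1=df1, df2=df2,
                         MS=ms_eff, F=float(F), p=p, eps_gg=eps, p_gg=p_gg))
    out = pd.DataFrame(rows)
    out.attrs["factor_a"] = factor_a
    out.attrs["factor_b"] = factor_b
    return out


def build_anova_table(fold_results: list[FoldResult], direction: str,
                      stratum: str = "overall") -> pd.DataFrame:
    """Tidy (subject, model, condition, rmse) table for the ANOVA."""
    rows = []
    for fr in fold_results:
        m = fr.metrics.get((stratum, direction))
        if m is not None:
            rows.append(dict(subject=fr.held_out_subject, model=fr.model_name,
                             condition=fr.condition, rmse=m.rmse))
    return pd.DataFrame(rows)
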