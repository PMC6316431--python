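"""Statistical layer: correlation, rank and t tests, distribution
summaries, and PCA-based plate-effect assessment.

The exact Mann-Whitney null distribution is computed here by the classic
count recursion N(m, n, u) = N(m, n-1, u) + N(m-1, n, u-n); everything
standard (t and normal tails, Kruskal-Wallis, SVD, midranks) goes through
scipy/numpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import Dataset
from .simulate import ElisaTable

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "PlateEffectResult",
    "pearson",
    "wilcoxon_rank_sum",
    "t_test",
    "median_iqr",
    "pca_plate_assoc",
    "validate_against_reference",
    "group_compare",
]

#: largest combined group size for which the exact rank-sum tail is used
EXACT_WILCOXON_MAX_N = 14


@dataclass
class CorrelationResult:
    analyte: str
    reference: str
    transform: str
    n: int
    pearson_r: float
    p_two_sided: float

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "reference": self.reference,
            "transform": self.transform,
            "n": self.n,
            "pearson_r": self.pearson_r,
            "p_two_sided": self.p_two_sided,
        }


@dataclass
class GroupComparison:
    analyte: str
    grouping: str
    groups: dict[str, dict]  # level -> {n, median, q25, q75}
    test: str
    statistic: float
    p_two_sided: float

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "grouping": self.grouping,
            "groups": self.groups,
            "test": self.test,
            "statistic": self.statistic,
            "p_two_sided": self.p_two_sided,
        }


@dataclass
class PlateEffectResult:
    variance_explained: list[float]
    p_values: list[float]
    verdict: str  # "plate effect detected" | "no plate effect" | "not applicable"
    threshold: float = 0.01

    @property
    def detected(self) -> bool:
        return self.verdict == "plate effect detected"

    def to_dict(self) -> dict:
        return {
            "variance_explained": self.variance_explained,
            "p_values": self.p_values,
            "verdict": self.verdict,
            "threshold": self.threshold,
        }


# ---------------------------------------------------------------------------
# correlation


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-based p-value.

    r uses n-1 denominators; p comes from t = r*sqrt(n-2)/sqrt(1-r^2) on
    n-2 degrees of freedom; |r| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("pearson requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("pearson requires finite inputs")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("pearson undefined: zero variance in an input")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# rank-sum test


def _u_null_counts(nx: int, ny: int) -> np.ndarray:
    """Counts of arrangements for each value of the Mann-Whitney U of the
    first group, via N(m,n,u) = N(m,n-1,u) + N(m-1,n,u-n)."""
    maxu = nx * ny
    # rows m=0..nx at current n; start at n = 0 where only U=0 is possible
    table = [np.zeros(maxu + 1) for _ in range(nx + 1)]
    for m in range(nx + 1):
        table[m][0] = 1.0
    for n in range(1, ny + 1):
        new = [np.zeros(maxu + 1) for _ in range(nx + 1)]
        new[0][0] = 1.0
        for m in range(1, nx + 1):
            new[m][:] = table[m]  # N(m, n-1, u)
            new[m][n:] += new[m - 1][:-n]  # N(m-1, n, u-n)
        table = new
    return table[nx]


def wilcoxon_rank_sum(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sample rank-sum test; returns (U of x, two-sided p).

    Midranks handle ties. ``method`` is ``"exact"`` (full null enumeration;
    requires tie-free data), ``"normal"`` (tie- and continuity-corrected
    Gaussian tail) or ``"auto"``: exact when nx+ny <= 14 without ties,
    normal otherwise. Two-sided p = min(1, 2*min(tail probabilities)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("wilcoxon_rank_sum: both groups must be nonempty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    rank_sum_x = ranks[:nx].sum()
    u = float(rank_sum_x - nx * (nx + 1) / 2.0)

    has_ties = np.unique(combined).size < combined.size
    if method == "auto":
        method = "exact" if (nx + ny <= EXACT_WILCOXON_MAX_N and not has_ties) else "normal"
    if method == "exact":
        if has_ties:
            raise ValueError("exact rank-sum method requires tie-free data")
        counts = _u_null_counts(nx, ny)
        total = counts.sum()
        k = int(round(u))
        lower = counts[: k + 1].sum() / total
        upper = counts[k:].sum() / total
        return u, float(min(1.0, 2.0 * min(lower, upper)))
    if method != "normal":
        raise ValueError(f"unknown method '{method}'")

    n = nx + ny
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0  # all values identical
    diff = u - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / np.sqrt(sigma2)
    return u, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# t test


def t_test(x, y, variant: str = "student") -> tuple[float, float]:
    """Two-sample t test: pooled-variance Student's t by default, Welch
    optional. Raises on zero pooled variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("t_test requires n >= 2 per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if variant == "student":
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        if pooled == 0.0:
            raise ValueError("t_test undefined: zero pooled variance")
        se = np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
        df = nx + ny - 2
    elif variant == "welch":
        se2 = vx / nx + vy / ny
        if se2 == 0.0:
            raise ValueError("t_test undefined: zero variance")
        se = np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    else:
        raise ValueError(f"unknown variant '{variant}'")
    t = float((x.mean() - y.mean()) / se)
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), df=df)))
    return t, p


# ---------------------------------------------------------------------------
# summaries


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q25, q75) by linear interpolation of order statistics at
    positions 1 + (n-1)q."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("median_iqr: empty input")
    q50, q25, q75 = np.percentile(values, [50, 25, 75], method="linear")
    return float(q50), float(q25), float(q75)


# ---------------------------------------------------------------------------
# plate effect


def pca_plate_assoc(
    log_matrix, plate_labels, k: int = 2, threshold: float = 0.01
) -> PlateEffectResult:
    """PCA of the column-centered samples x analytes matrix, then a
    Kruskal-Wallis association of each of the first *k* PC score vectors
    with the plate label. Verdict: "plate effect detected" iff any of the
    k p-values falls below ``threshold``; a single plate is "not applicable".
    """
    X = (
        log_matrix.to_numpy(dtype=float)
        if isinstance(log_matrix, pd.DataFrame)
        else np.asarray(log_matrix, dtype=float)
    )
    labels = np.asarray(plate_labels)
    if X.shape[0] != labels.size:
        raise ValueError("plate_labels length must match the number of rows")
    if X.shape[0] < 2:
        raise ValueError("pca_plate_assoc requires >= 2 samples")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(X.shape)}")

    Xc = X - X.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    var_frac = [float(v) for v in (s**2 / total if total > 0 else s * 0.0)[:k]]
    scores = Xc @ vt[:k].T

    levels = pd.unique(labels)
    if len(levels) < 2:
        return PlateEffectResult(var_frac, [], "not applicable", threshold)

    p_values = []
    for j in range(k):
        groups = [scores[labels == lv, j] for lv in levels]
        if any(g.size == 0 for g in groups) or np.ptp(scores[:, j]) == 0:
            p_values.append(1.0)
            continue
        p_values.append(float(sps.kruskal(*groups).pvalue))
    verdict = (
        "plate effect detected" if any(p < threshold for p in p_values) else "no plate effect"
    )
    return PlateEffectResult(var_frac, p_values, verdict, threshold)


# ---------------------------------------------------------------------------
# cross-platform validation and group comparison


def validate_against_reference(
    dataset: Dataset,
    elisa: ElisaTable,
    analyte_map: dict[str, str] | None = None,
    transform: str = "log2",
    roles: tuple[str, ...] = ("study",),
    quantile: bool = False,
) -> list[CorrelationResult]:
    """Pearson correlation between platform RFU and reference-assay
    concentration, per analyte, joined by sample id.

    ``analyte_map`` maps platform seq_ids to reference table seq_ids
    (identity by default). Both sides are log2-transformed unless
    ``transform="raw"``; with ``quantile=True`` the platform side is
    additionally quantile-normalized across the selected samples first
    (the transform sequence the downstream statistics use). Analytes with
    fewer than 3 overlapping samples are skipped with a warning.
    """
    if transform not in ("log2", "raw"):
        raise ValueError(f"unknown transform '{transform}'")
    rows = dataset.sample_ids(*roles)
    platform = dataset.rfu
    if quantile:
        from .normalize import quantile_normalize

        platform = platform.copy()
        prot = dataset.protein_ids
        platform.loc[rows, prot] = quantile_normalize(platform.loc[rows, prot])
    ref_ids = sorted(elisa.values["seq_id"].unique())
    if analyte_map is None:
        analyte_map = {a: a for a in ref_ids if a in dataset.rfu.columns}
    results = []
    for platform_id, ref_id in analyte_map.items():
        conc = elisa.concentrations(ref_id)
        common = [s for s in rows if s in conc.index]
        if len(common) < 3:
            warnings.warn(
                f"analyte '{platform_id}': only {len(common)} overlapping samples, skipped"
            )
            continue
        xs = platform.loc[common, platform_id].to_numpy()
        ys = conc.loc[common].to_numpy()
        if transform == "log2":
            xs, ys = np.log2(xs), np.log2(ys)
        r, p = pearson(xs, ys)
        results.append(
            CorrelationResult(
                analyte=platform_id,
                reference=ref_id,
                transform=("qn+" + transform) if quantile else transform,
                n=len(common),
                pearson_r=r,
                p_two_sided=p,
            )
        )
    return results


def group_compare(
    dataset: Dataset,
    analyte: str,
    grouping: str = "sex",
    test: str = "wilcoxon",
    roles: tuple[str, ...] = ("study",),
    transform: str = "log2",
) -> GroupComparison:
    """Two-group comparison of one analyte among study samples.

    Group summaries (median and IQR) are reported on the untransformed
    normalized RFU scale; the hypothesis test runs on transformed values.
    ``grouping`` is ``"sex"`` or the name of a ``group:*`` roster column.
    """
    rows = dataset.sample_ids(*roles)
    col = grouping if grouping in dataset.samples.columns else f"group:{grouping}"
    if col not in dataset.samples.columns:
        raise ValueError(f"unknown grouping '{grouping}'")
    labels = dataset.samples.loc[rows, col]
    levels = [lv for lv in pd.unique(labels) if lv not in ("", "unknown")]
    if len(levels) != 2:
        raise ValueError(
            f"grouping '{grouping}' must have exactly 2 levels among study samples, "
            f"got {list(levels)}"
        )
    values = dataset.rfu.loc[rows, analyte]
    groups = {}
    sides = []
    for lv in levels:
        vals = values[labels == lv].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"group '{lv}' is empty")
        med, q25, q75 = median_iqr(vals)
        groups[str(lv)] = {"n": int(vals.size), "median": med, "q25": q25, "q75": q75}
        sides.append(np.log2(vals) if transform == "log2" else vals)
    if test == "wilcoxon":
        stat, p = wilcoxon_rank_sum(sides[0], sides[1])
    elif test == "t":
        stat, p = t_test(sides[0], sides[1])
    else:
        raise ValueError(f"unknown test '{test}'")
    return GroupComparison(
        analyte=analyte,
        grouping=grouping,
        groups=groups,
        test=test,
        statistic=float(stat),
        p_two_sided=float(p),
    )
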