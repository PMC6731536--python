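"""Statistical procedures used by the pipeline.

The factorial workhorse is the aligned rank transform (ART) two-way ANOVA: a
nonparametric test of main and interaction effects in which, for each effect,
the response is "aligned" (all other estimated effects and the grand mean are
subtracted), converted to midranks, and submitted to a classical two-way
fixed-effects ANOVA; only the aligned-for effect's p-value is read off.  This
lets a rank test ask "does maturation change the response, independent of the
registration-parameter nuisance factor, and without a maturation x
registration interaction?".

Rank-sum, Welch and OLS tests delegate to scipy behind this module's surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import stats

__all__ = [
    "RankTestResult",
    "FactorialResult",
    "mann_whitney",
    "art_anova_2way",
    "bonferroni_flags",
    "welch_t",
    "ols_fit",
]

EXACT_MAX_NM = 400  # n*m above which the normal approximation is used


@dataclass(frozen=True)
class RankTestResult:
    """Two-sided Mann-Whitney U outcome."""

    U: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"


@dataclass
class FactorialResult:
    """Two-way factorial test result (A = maturation, B = nuisance factor)."""

    p_main_A: float
    p_main_B: float
    p_interaction: float
    F_main_A: float = np.nan
    F_main_B: float = np.nan
    F_interaction: float = np.nan
    df: dict = field(default_factory=dict)
    flag_significant: bool = False

    def apply_flag(self, alpha_corrected: float, alpha_interaction: float = 0.05) -> "FactorialResult":
        """Flag iff the A main effect clears ``alpha_corrected`` AND the
        interaction does not reach ``alpha_interaction``."""
        self.flag_significant = (
            self.p_main_A < alpha_corrected
            and self.p_interaction >= alpha_interaction
        )
        return self


def mann_whitney(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration is used for small untied samples (n*m <= 400); a
    tie-corrected normal approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size * y.size <= EXACT_MAX_NM and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approx"
    return RankTestResult(U=float(res.statistic), p_two_sided=float(res.pvalue), method=method)


def welch_t(x, y) -> tuple[float, float]:
    """Welch's unequal-variance t test with Satterthwaite df; returns (t, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least 2 observations per sample")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def ols_fit(x, y) -> tuple[float, float]:
    """Ordinary least-squares line fit; returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("ols_fit requires at least two distinct x values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def bonferroni_flags(p_values, alpha: float) -> np.ndarray:
    """Boolean flags p_i < alpha/m for the m supplied p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("bonferroni_flags requires at least one p-value")
    return p < alpha / p.size


# -- ART two-way ANOVA ---------------------------------------------------------


def _midrank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _design_matrices(a_codes: np.ndarray, b_codes: np.ndarray, na: int, nb: int):
    """Sum-to-zero (effect-coded) design columns for A, B and A:B."""
    n = a_codes.size
    A = np.zeros((n, na - 1))
    for lvl in range(na - 1):
        A[a_codes == lvl, lvl] = 1.0
        A[a_codes == na - 1, lvl] = -1.0
    B = np.zeros((n, nb - 1))
    for lvl in range(nb - 1):
        B[b_codes == lvl, lvl] = 1.0
        B[b_codes == nb - 1, lvl] = -1.0
    AB = np.einsum("ij,ik->ijk", A, B).reshape(n, (na - 1) * (nb - 1))
    return A, B, AB


def _orth_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal column basis of X (rank-revealing via SVD)."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    return u[:, :rank]

# Per-voxel/per-shell tests reuse one factorial layout hundreds of times, so
# the orthonormal bases of the four models are cached per design.
_DESIGN_CACHE: dict[bytes, tuple] = {}


def _rss_q(Q: np.ndarray, y: np.ndarray) -> float:
    proj = Q.T @ y
    return float(y @ y - proj @ proj)


def _anova_on(y: np.ndarray, bases, df_a, df_b, df_ab):
    """Type-III F tests of A, B, A:B on response y; returns Fs, ps, df_resid."""
    n = y.size
    q_full, q_red = bases
    df_resid = n - q_full.shape[1]
    rss_full = _rss_q(q_full, y)
    out_F, out_p = [], []
    for drop, df_eff in (("A", df_a), ("B", df_b), ("AB", df_ab)):
        ss_eff = max(_rss_q(q_red[drop], y) - rss_full, 0.0)
        if df_resid <= 0 or rss_full <= 1e-12 * max(1.0, float(y @ y)):
            # no residual variance: degenerate, report p = 1 unless the effect
            # itself carries all the variance
            if ss_eff > 1e-10:
                out_F.append(np.inf)
                out_p.append(0.0)
            else:
                out_F.append(0.0)
                out_p.append(1.0)
            continue
        F = (ss_eff / df_eff) / (rss_full / df_resid)
        p = float(stats.f.sf(F, df_eff, df_resid))
        out_F.append(float(F))
        out_p.append(p)
    return out_F, out_p, df_resid


def art_anova_2way(response, factor_a, factor_b) -> FactorialResult:
    """Aligned rank transform two-way ANOVA.

    Parameters
    ----------
    response
        Numeric observations.
    factor_a, factor_b
        Factor level labels, one per observation.  A is the factor of interest
        (maturation); B the nuisance factor (registration-parameter set).

    Notes
    -----
    Alignment uses cell/marginal means of the raw response: for each effect the
    estimated other effects and the grand mean are subtracted, the aligned
    values are midranked, and a classical two-way fixed-effects ANOVA
    (Type-III-style model comparison on effect-coded designs, so unbalanced
    cells are handled) is run on the ranks; only that effect's p is reported.
    """
    y = np.asarray(response, dtype=float)
    a_raw = np.asarray(factor_a)
    b_raw = np.asarray(factor_b)
    if not (y.size == a_raw.size == b_raw.size):
        raise ValueError("response and factor arrays must have equal length")
    a_levels, a_codes = np.unique(a_raw, return_inverse=True)
    b_levels, b_codes = np.unique(b_raw, return_inverse=True)
    na, nb = a_levels.size, b_levels.size
    if na < 2 or nb < 2:
        raise ValueError("each factor needs >= 2 levels")
    # cell means; every cell must be populated
    counts = np.zeros((na, nb))
    sums = np.zeros((na, nb))
    np.add.at(counts, (a_codes, b_codes), 1.0)
    np.add.at(sums, (a_codes, b_codes), y)
    empty = np.argwhere(counts == 0)
    if empty.size:
        ai, bi = empty[0]
        raise ValueError(
            f"empty cell: A={a_levels[ai]!r} x B={b_levels[bi]!r}"
        )
    cell = sums / counts
    # unweighted marginal means of cell means (least-squares means)
    mu_a = cell.mean(axis=1)
    mu_b = cell.mean(axis=0)
    mu = cell.mean()

    resid = y - cell[a_codes, b_codes]
    aligned = {
        "A": resid + mu_a[a_codes] - mu,
        "B": resid + mu_b[b_codes] - mu,
        "AB": resid + cell[a_codes, b_codes] - mu_a[a_codes] - mu_b[b_codes] + mu,
    }

    df_a, df_b, df_ab = na - 1, nb - 1, (na - 1) * (nb - 1)
    key = a_codes.astype(np.int32).tobytes() + b"|" + b_codes.astype(np.int32).tobytes()
    if key in _DESIGN_CACHE:
        bases = _DESIGN_CACHE[key]
    else:
        A, B, AB = _design_matrices(a_codes, b_codes, na, nb)
        ones = np.ones((y.size, 1))
        bases = (
            _orth_basis(np.hstack([ones, A, B, AB])),
            {
                "A": _orth_basis(np.hstack([ones, B, AB])),
                "B": _orth_basis(np.hstack([ones, A, AB])),
                "AB": _orth_basis(np.hstack([ones, A, B])),
            },
        )
        if len(_DESIGN_CACHE) > 64:
            _DESIGN_CACHE.clear()
        _DESIGN_CACHE[key] = bases

    ps = {}
    Fs = {}
    df_resid = y.size - na * nb
    for eff in ("A", "B", "AB"):
        ranked = _midrank(aligned[eff])
        if np.ptp(ranked) == 0:  # constant aligned response
            ps[eff], Fs[eff] = 1.0, 0.0
            continue
        F3, p3, df_resid = _anova_on(ranked, bases, df_a, df_b, df_ab)
        idx = ("A", "B", "AB").index(eff)
        ps[eff], Fs[eff] = p3[idx], F3[idx]

    return FactorialResult(
        p_main_A=ps["A"],
        p_main_B=ps["B"],
        p_interaction=ps["AB"],
        F_main_A=Fs["A"],
        F_main_B=Fs["B"],
        F_interaction=Fs["AB"],
        df={"A": df_a, "B": df_b, "AB": df_ab, "resid": df_resid},
    )
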