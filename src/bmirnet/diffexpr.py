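"""Differential expression of miRNAs in B+ vs B- samples.

One contrast per tissue x sex combination, always with the B- group as
control. The engine is the classical negative-binomial exact test at a fixed
common dispersion phi = BCV^2 (BCV 0.4 by default): effective library sizes
are equalized, the test conditions on each miRNA's total count, and sums the
conditional probabilities of outcomes as or more extreme than the observed
split. Library composition is corrected by TMM (weighted trimmed mean of
M-values) normalization; low-expression rows are removed by a CPM filter
first. A miRNA is called differentially expressed at raw p < 0.05 and linear
|fold change| > 1.5; an optional Benjamini-Hochberg adjustment is available
but off by default.

The conditional null: with n_a and n_b samples per group at common
dispersion phi, each group total is NB with size n_g / phi and a shared
success probability, so the split of the row total follows a beta-binomial
(negative hypergeometric) law that does not depend on the unknown mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

#: prior count added to normalized group means before the log2 ratio
PRIOR_COUNT = 0.125


@dataclass
class DEResult:
    mirna_id: str
    contrast: tuple[str, str]  # (tissue, sex)
    log2fc: float
    fold_change: float  # signed linear convention: +FC up, -FC down, |FC| >= 1
    p_value: float
    is_de: bool = False
    direction: str | None = None
    q_value: float | None = None


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def cpm_filter(counts: pd.DataFrame, cpm_min: float = 1.0, min_samples: int = 6) -> pd.DataFrame:
    """Retain rows with CPM >= cpm_min in at least min_samples samples."""
    if min_samples > counts.shape[1]:
        raise ValueError(f"min_samples={min_samples} exceeds {counts.shape[1]} samples")
    lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        raise ValueError("every library must have a positive total count")
    cpm = counts * 1e6 / lib_sizes
    keep = (cpm >= cpm_min).sum(axis=1) >= min_samples
    return counts.loc[keep]


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """TMM normalization factors (weighted trimmed mean of M-values).

    The reference sample is the library whose 75th count percentile (scaled
    by library size) is closest to the mean across libraries. For each
    sample, gene-wise log2 ratios M and average abundances A against the
    reference are doubly trimmed by rank (trim_m on M, trim_a on A) and the
    surviving M values averaged with inverse asymptotic-variance weights.
    Factors are rescaled so their log-mean is zero (product = 1).
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("every library must have a positive total count")
    y = counts.to_numpy(dtype=float)
    uq = np.array([np.quantile(y[:, k] / lib[k], 0.75) for k in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    for k in range(y.shape[1]):
        factors[k] = _tmm_pair(y[:, k], y[:, ref], lib[k], lib[ref], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    o, r = obs[ok], ref[ok]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # inverse asymptotic variance of M (delta method, binomial sampling)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


# ---------------------------------------------------------------------------
# NB exact test at fixed dispersion
# ---------------------------------------------------------------------------

def _exact_p(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Conditional two-sided exact p for a count split at dispersion phi.

    Conditions on the total t = sum_a + sum_b. The split follows a
    beta-binomial law with shape parameters r_a = n_a/phi, r_b = n_b/phi
    (Poisson/binomial limit when phi = 0). Two-sided p sums the probabilities
    of all splits as or less probable than the observed one.
    """
    t = sum_a + sum_b
    if t == 0:
        return 1.0
    x = np.arange(t + 1)
    if phi <= 0:
        # Poisson limit: binomial split with prob n_a / (n_a + n_b)
        pr = n_a / (n_a + n_b)
        logp = (
            gammaln(t + 1) - gammaln(x + 1) - gammaln(t - x + 1)
            + x * np.log(pr) + (t - x) * np.log1p(-pr)
        )
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logp = (
            gammaln(x + r_a) - gammaln(x + 1) - gammaln(r_a)
            + gammaln(t - x + r_b) - gammaln(t - x + 1) - gammaln(r_b)
        )
        logp = logp - _logsumexp(logp)
    p_obs = logp[sum_a]
    mask = logp <= p_obs + 1e-10
    return float(min(1.0, np.exp(_logsumexp(logp[mask]) - _logsumexp(logp))))


def _logsumexp(v: np.ndarray) -> float:
    m = np.max(v)
    return float(m + np.log(np.sum(np.exp(v - m))))


def exact_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    bcv: float = 0.4,
    norm_factors: pd.Series | None = None,
) -> list[DEResult]:
    """Per-miRNA NB exact test for one (tissue, sex) contrast, B+ vs B-.

    Effective library sizes (library size x TMM factor) are equalized by
    scaling each group's total count to the geometric-mean effective size
    before conditioning. log2 fold change is computed from normalized group
    means with a prior count of 0.125 on each side.
    """
    tissue, sex = contrast
    sel = design[(design["tissue"] == tissue) & (design["sex"] == sex)]
    cols_a = sel.loc[sel["b_status"] == "Bminus", "sample_id"].tolist()
    cols_b = sel.loc[sel["b_status"] == "Bplus", "sample_id"].tolist()
    if not cols_a or not cols_b:
        raise ValueError(f"contrast {contrast}: a group has no samples")
    sub = counts[cols_a + cols_b]
    if norm_factors is None:
        norm_factors = tmm_factors(sub) if sub.shape[1] >= 2 else pd.Series(1.0, index=sub.columns)
    eff = sub.sum(axis=0).to_numpy(dtype=float) * norm_factors[sub.columns].to_numpy()
    common = float(np.exp(np.mean(np.log(eff))))
    scale = common / eff
    y = sub.to_numpy(dtype=float)
    n_a, n_b = len(cols_a), len(cols_b)
    sums_a = np.rint((y[:, :n_a] * scale[:n_a]).sum(axis=1)).astype(int)
    sums_b = np.rint((y[:, n_a:] * scale[n_a:]).sum(axis=1)).astype(int)
    phi = bcv ** 2

    mean_a = (y[:, :n_a] * scale[:n_a]).mean(axis=1)
    mean_b = (y[:, n_a:] * scale[n_a:]).mean(axis=1)
    log2fc = np.log2(mean_b + PRIOR_COUNT) - np.log2(mean_a + PRIOR_COUNT)

    results = []
    for gi, mid in enumerate(sub.index):
        p = _exact_p(int(sums_a[gi]), int(sums_b[gi]), n_a, n_b, phi)
        lfc = float(log2fc[gi])
        linear = 2.0 ** abs(lfc)
        fc = linear if lfc >= 0 else -linear
        results.append(DEResult(str(mid), contrast, lfc, fc, p))
    return results


def call_de(
    results: list[DEResult],
    alpha: float = 0.05,
    fc_min: float = 1.5,
    adjust_bh: bool = False,
) -> list[DEResult]:
    """Apply the DE decision rule: p < alpha and linear |FC| > fc_min.

    With ``adjust_bh`` the Benjamini-Hochberg q-value replaces the raw p in
    the decision (off by default: the DE call is on raw p-values).
    """
    if adjust_bh and results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    for r in results:
        p_used = r.q_value if adjust_bh else r.p_value
        r.is_de = bool(p_used < alpha and abs(r.fold_change) > fc_min)
        r.direction = ("up" if r.log2fc > 0 else "down") if r.is_de else None
    return results


def nonredundant_de(
    per_contrast: dict[tuple[str, str], list[DEResult]],
) -> tuple[set[str], dict[str, set[tuple[str, str]]], dict[str, int]]:
    """Union of DE miRNA ids over contrasts, with membership and Venn counts.

    Returns (union, membership, tissue_venn): membership maps each DE miRNA
    to the contrasts it was called in; tissue_venn counts the union by
    tissue-combination key (e.g. "brain", "brain+gonad").
    """
    if not per_contrast:
        raise ValueError("at least one contrast required")
    membership: dict[str, set[tuple[str, str]]] = {}
    for contrast, results in per_contrast.items():
        for r in results:
            if r.is_de:
                membership.setdefault(r.mirna_id, set()).add(contrast)
    union = set(membership)
    venn: dict[str, int] = {}
    for mid, contrasts in membership.items():
        key = "+".join(sorted({tissue for tissue, _ in contrasts}))
        venn[key] = venn.get(key, 0) + 1
    return union, membership, venn


def results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in results],
            "tissue": [r.contrast[0] for r in results],
            "sex": [r.contrast[1] for r in results],
            "log2fc": [r.log2fc for r in results],
            "fold_change": [r.fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "is_de": [r.is_de for r in results],
            "direction": [r.direction for r in results],
        }
    )
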