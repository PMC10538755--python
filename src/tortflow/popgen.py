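"""Population-genetic summary statistics on genotype snapshots.

Implements the analysis battery applied to simulation output: subsampling,
observed/expected heterozygosity and allelic richness, pairwise
Weir-Cockerham (1984) theta between barrier sides, the linkage-disequilibrium
effective-population-size estimator (Burrows composite disequilibrium with
the Waples sample-size bias correction, random-mating model, parametric
chi-square confidence intervals), Hardy-Weinberg exact tests by Monte-Carlo
allele permutation, and paired across-locus t comparisons.

All estimators require complete genotypes (the simulator generates no
missing data) and reject missing entries loudly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

DEFAULT_SAMPLE_SIZE = 750
PCRIT = 0.05


@dataclass
class GenotypeSample:
    """Subsampled genotypes with group labels (side of the barrier)."""

    genotypes: np.ndarray  # (n, n_loci, 2)
    groups: np.ndarray  # int labels, 0/1 (or all 0 for a pooled sample)
    locus_ids: list[str] | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes)
        self.groups = np.asarray(self.groups)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n, loci, 2)")
        if len(self.groups) != len(self.genotypes):
            raise ValueError("group labels must match genotypes")
        if np.any(self.genotypes <= 0):
            raise ValueError("missing or non-positive allele states not supported")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class DiversityStats:
    ho: float
    he: float
    ar: float
    ho_sd: float
    he_sd: float
    ar_sd: float
    per_locus_ho: np.ndarray
    per_locus_he: np.ndarray
    per_locus_ar: np.ndarray


@dataclass
class NeEstimate:
    point: float  # may be inf
    ci_low: float
    ci_high: float
    r2_prime: float
    n_comparisons: int
    sample_size: int


def subsample(state_or_sample, n: int = DEFAULT_SAMPLE_SIZE, seed=None,
              surface=None) -> GenotypeSample:
    """Uniform sample without replacement, grouped by barrier side.

    Accepts a simulator ``PopulationState`` (with a surface for side labels)
    or a prebuilt ``GenotypeSample``. When the snapshot holds fewer than
    ``n`` individuals the whole snapshot is returned (with a warning logged
    via the returned sample size).
    """
    rng = np.random.default_rng(seed)
    if isinstance(state_or_sample, GenotypeSample):
        genotypes, groups = state_or_sample.genotypes, state_or_sample.groups
    else:
        state = state_or_sample
        genotypes = state.genotypes
        if surface is not None:
            groups = surface.side_of(state.col)
        else:
            groups = np.zeros(len(genotypes), dtype=int)
    total = len(genotypes)
    if total > n:
        idx = np.sort(rng.choice(total, size=n, replace=False))
        genotypes, groups = genotypes[idx], np.asarray(groups)[idx]
    return GenotypeSample(genotypes=genotypes.copy(), groups=np.asarray(groups))


def diversity(sample: GenotypeSample) -> DiversityStats:
    """Per-locus Ho, unbiased He (Nei, 2n/(2n-1) correction), allele counts.

    Means and SDs are taken over loci.
    """
    g = sample.genotypes
    n, L, _ = g.shape
    if n < 1:
        raise ValueError("empty sample")
    ho = np.empty(L)
    he = np.empty(L)
    ar = np.empty(L)
    for j in range(L):
        a = g[:, j, :]
        ho[j] = np.mean(a[:, 0] != a[:, 1])
        alleles, counts = np.unique(a, return_counts=True)
        p = counts / (2 * n)
        he[j] = (1.0 - np.sum(p**2)) * (2 * n) / (2 * n - 1) if n > 0 else 0.0
        if len(alleles) == 1:
            he[j] = 0.0
        ar[j] = len(alleles)
    return DiversityStats(
        ho=float(ho.mean()), he=float(he.mean()), ar=float(ar.mean()),
        ho_sd=float(ho.std(ddof=1)) if L > 1 else 0.0,
        he_sd=float(he.std(ddof=1)) if L > 1 else 0.0,
        ar_sd=float(ar.std(ddof=1)) if L > 1 else 0.0,
        per_locus_ho=ho, per_locus_he=he, per_locus_ar=ar,
    )


def pairwise_fst(sample: GenotypeSample) -> float:
    """Multilocus Weir-Cockerham (1984) theta between the two groups.

    Computes the a (among-population), b (among-individual) and c
    (within-individual) variance components per allele per locus and returns
    ``sum(a) / sum(a + b + c)`` over all alleles and loci.
    """
    labels = np.unique(sample.groups)
    if len(labels) != 2:
        raise ValueError("pairwise theta needs exactly two groups")
    g1 = sample.genotypes[sample.groups == labels[0]]
    g2 = sample.genotypes[sample.groups == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least two individuals")
    num = 0.0
    den = 0.0
    for j in range(sample.n_loci):
        a, b, c = _wc_components(g1[:, j, :], g2[:, j, :])
        num += a.sum()
        den += (a + b + c).sum()
    return float(num / den) if den > 0 else 0.0


def _wc_components(a1: np.ndarray, a2: np.ndarray):
    """WC84 per-allele variance components for one locus, two populations."""
    r = 2
    n_i = np.array([len(a1), len(a2)], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([a1.ravel(), a2.ravel()]))
    a_out = np.zeros(len(alleles))
    b_out = np.zeros(len(alleles))
    c_out = np.zeros(len(alleles))
    for k, al in enumerate(alleles):
        p_i = np.array(
            [np.mean(a1 == al), np.mean(a2 == al)]
        )
        h_i = np.array(
            [np.mean((a1[:, 0] == al) != (a1[:, 1] == al)),
             np.mean((a2[:, 0] == al) != (a2[:, 1] == al))]
        )
        pbar = np.sum(n_i * p_i) / np.sum(n_i)
        s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n_i * h_i) / np.sum(n_i)
        a_k = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b_k = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c_k = hbar / 2
        a_out[k], b_out[k], c_out[k] = a_k, b_k, c_k
    return a_out, b_out, c_out


# ---------------------------------------------------------------------------
# LD-based effective population size

def ld_ne(sample: GenotypeSample, pcrit: float = PCRIT) -> NeEstimate:
    """LD effective size: Burrows composite r^2, random-mating model.

    Alleles with sample frequency below ``pcrit`` are screened out per locus;
    loci left with fewer than two alleles are dropped. For every locus pair
    and every retained allele pair, the Burrows composite disequilibrium is

        Delta = cov(X, Y) / 2  (dosage covariance), scaled by S/(S-1),

    and r^2 = Delta^2 / (v_A v_B) with v = p(1-p) + (P_hom - p^2). The mean
    r^2 minus its sample-size expectation E[r^2|S] = 1/S + 3.19/S^2 (S >= 30)
    gives r2'; then Ne = (1/3 + sqrt(1/9 - 2.76 r2')) / (2 r2'). Non-positive
    r2' yields infinity. The parametric 95% CI treats J * mean(r^2) / r^2 as
    chi-square with J degrees of freedom (J = number of allele-pair
    comparisons).
    """
    g = sample.genotypes
    S, L, _ = g.shape
    if S < 2:
        raise ValueError("need at least two individuals")

    # dosage matrices per locus for retained alleles
    dosages = []  # list of (n_alleles_kept, S) arrays
    vars_ = []
    for j in range(L):
        a = g[:, j, :]
        alleles, counts = np.unique(a, return_counts=True)
        freqs = counts / (2 * S)
        keep = alleles[freqs >= pcrit]
        if len(keep) < 2:
            continue
        # with k retained alleles only k-1 carry independent information:
        # drop the most common retained allele so J counts independent
        # comparisons (the parametric CI treats J as chi-square df)
        kept_freqs = freqs[np.isin(alleles, keep)]
        keep = np.delete(keep, np.argmax(kept_freqs))
        if len(keep) == 0:
            continue
        X = (a[:, 0][None, :] == keep[:, None]).astype(float) + (
            a[:, 1][None, :] == keep[:, None]
        )
        p = X.mean(axis=1) / 2
        hom = ((a[:, 0][None, :] == keep[:, None])
               & (a[:, 1][None, :] == keep[:, None])).mean(axis=1)
        v = p * (1 - p) + (hom - p**2)
        ok = v > 0
        if ok.sum() == 0:
            continue
        dosages.append(X[ok])
        vars_.append(v[ok])

    if len(dosages) < 2:
        raise ValueError("fewer than 2 usable loci after allele screening")

    r2_values = []
    for i in range(len(dosages)):
        for j in range(i + 1, len(dosages)):
            Xi, Xj = dosages[i], dosages[j]
            Xic = Xi - Xi.mean(axis=1, keepdims=True)
            Xjc = Xj - Xj.mean(axis=1, keepdims=True)
            cov = Xic @ Xjc.T / S  # (ai, aj)
            delta = cov / 2.0 * S / (S - 1)
            r2 = delta**2 / np.outer(vars_[i], vars_[j])
            r2_values.append(r2.ravel())
    r2_all = np.concatenate(r2_values)
    J = len(r2_all)
    r2_mean = float(r2_all.mean())

    exp_r2 = _expected_r2(S)
    point = _ne_from_r2prime(r2_mean - exp_r2)

    # parametric CI on mean r^2, then through the Ne transform; the df is
    # the number of locus-pair comparisons (allele-level r^2 values within a
    # locus pair are strongly dependent)
    df = len(r2_values)
    lo_r2 = df * r2_mean / sps.chi2.ppf(0.975, df)
    hi_r2 = df * r2_mean / sps.chi2.ppf(0.025, df)
    ci_low = _ne_from_r2prime(hi_r2 - exp_r2)
    ci_high = _ne_from_r2prime(lo_r2 - exp_r2)
    if ci_low > ci_high:
        ci_low, ci_high = ci_high, ci_low
    return NeEstimate(
        point=point, ci_low=min(ci_low, point), ci_high=max(ci_high, point),
        r2_prime=r2_mean - exp_r2, n_comparisons=J, sample_size=S,
    )


def _expected_r2(S: int) -> float:
    """Expected r^2 from finite sample size alone (random mating)."""
    if S >= 30:
        return 1.0 / S + 3.19 / S**2
    return 0.0018 + 0.907 / S + 4.44 / S**2


def _ne_from_r2prime(r2p: float) -> float:
    if r2p <= 0:
        return float("inf")
    disc = 1.0 / 9.0 - 2.76 * r2p
    if disc < 0:
        disc = 0.0
    return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2p)


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests

def hwe_test(sample: GenotypeSample, n_perm: int = 10000, seed=None,
             n_loci_bonferroni: int | None = None):
    """Per-locus HWE exact test by Monte-Carlo permutation of alleles.

    The 2n alleles at a locus are shuffled and re-paired; the statistic is
    the chi-square distance of genotype counts from their permutation-mean,
    and p = (1 + #{perm >= obs}) / (1 + n_perm). Returns (p_values,
    bonferroni_threshold, verdict) where the verdict is True when every
    locus clears the Bonferroni-corrected 0.05 threshold.
    """
    if sample.n < 5:
        raise ValueError("need at least 5 individuals")
    rng = np.random.default_rng(seed)
    g = sample.genotypes
    n, L, _ = g.shape
    pvals = np.ones(L)
    for j in range(L):
        a = g[:, j, :]
        alleles = np.unique(a)
        if len(alleles) == 1:
            pvals[j] = 1.0
            continue
        pool = a.ravel().copy()
        obs = _hwe_statistic(a[:, 0], a[:, 1], alleles, pool)
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pool)
            stat = _hwe_statistic(pool[:n], pool[n:], alleles, pool)
            if stat >= obs:
                count += 1
        pvals[j] = (1 + count) / (1 + n_perm)
    thresh = 0.05 / (n_loci_bonferroni or L)
    return pvals, thresh, bool(np.all(pvals > thresh))


def _hwe_statistic(a1, a2, alleles, pool) -> float:
    """Chi-square-style distance of genotype counts from HWE expectation."""
    n = len(a1)
    freqs = np.array([(pool == al).mean() for al in alleles])
    lo = np.minimum(a1, a2)
    hi = np.maximum(a1, a2)
    code = lo.astype(np.int64) * 10000 + hi
    stat = 0.0
    for i, ai in enumerate(alleles):
        for k in range(i, len(alleles)):
            ak = alleles[k]
            expect = n * (freqs[i] ** 2 if i == k else 2 * freqs[i] * freqs[k])
            if expect <= 0:
                continue
            obs = np.count_nonzero(
                code == int(min(ai, ak)) * 10000 + int(max(ai, ak))
            )
            stat += (obs - expect) ** 2 / expect
    return stat


def compare_across_loci(stats_a: np.ndarray, stats_b: np.ndarray):
    """Paired two-sided t-test across loci; returns (t, p, df)."""
    a = np.asarray(stats_a, dtype=float)
    b = np.asarray(stats_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("per-locus vectors must have equal length")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0, len(d) - 1
        raise ValueError("zero variance of non-zero differences (degenerate)")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p), len(d) - 1
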