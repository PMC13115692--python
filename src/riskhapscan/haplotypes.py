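"""EM haplotype-frequency inference over a few core SNPs from unphased
genotypes, case-control haplotype score tests, and a haplotype-dosage
Firth model with a reference haplotype.

The EM algorithm assumes Hardy-Weinberg proportions in the E-step (the
standard assumption for this estimator; a violation biases posteriors, not
the likelihood maximization itself, and is noted in the output). With
fully phase-unambiguous genotypes the solution reduces to direct counting.

The score test contrasts posterior-expected haplotype counts between cases
and controls. Conditional on genotypes, the expected counts are fixed
covariates, so under the null (status independent of genotype) the score
vector U_h = sum_i (y_i - ybar) e_ih has variance ybar(1-ybar) * centered
cross-product of the count matrix; the global statistic is the quadratic
form with a generalized inverse (df = number of haplotypes tested - 1,
reflecting the sum-to-2 constraint).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats

from .dosage import RiskModelFit, firth_logistic

__all__ = [
    "HaplotypeFreqs",
    "HaplotypeScoreResult",
    "em_haplotype_freqs",
    "haplo_score_test",
    "haplotype_dosage_model",
]


def _hap_label(bits, alleles=None, sep="-"):
    if alleles is None:
        return sep.join(str(b) for b in bits)
    return sep.join(alleles[j][b] for j, b in enumerate(bits))


def _enumerate_diplotypes(geno):
    """All ordered-insensitive haplotype pairs consistent with one genotype.

    ``geno`` is a length-k vector of alt-allele counts in {0,1,2}. Returns a
    list of (hap1_bits, hap2_bits) tuples (tuples of 0/1), hap1 <= hap2.
    """
    het = [j for j, g in enumerate(geno) if g == 1]
    base = [0 if g == 0 else 1 if g == 2 else None for g in geno]
    pairs = set()
    if not het:
        h = tuple(base)
        return [(h, h)]
    for assign in product((0, 1), repeat=len(het) - 1):
        # fix the first het site to break the mirror symmetry
        h1, h2 = list(base), list(base)
        h1[het[0]], h2[het[0]] = 0, 1
        for j, a in zip(het[1:], assign):
            h1[j], h2[j] = a, 1 - a
        pair = tuple(sorted((tuple(h1), tuple(h2))))
        pairs.add(pair)
    return sorted(pairs)


@dataclass
class HaplotypeFreqs:
    """EM haplotype frequencies and per-dog diplotype posteriors."""

    haplotypes: list          # tuples of 0/1 per SNP
    frequencies: np.ndarray
    diplotypes: list          # per dog: list of ((h1, h2), posterior)
    log_lik: float
    iterations: int
    converged: bool
    snp_alleles: list | None = None  # per SNP (ref, alt) for labelling

    def label(self, hap) -> str:
        return _hap_label(hap, self.snp_alleles)

    @property
    def labels(self) -> list:
        return [self.label(h) for h in self.haplotypes]

    def frequency_of(self, hap) -> float:
        return float(self.frequencies[self.haplotypes.index(tuple(hap))])

    def expected_counts(self) -> np.ndarray:
        """Posterior-expected haplotype counts per dog (n x H, rows sum to 2)."""
        index = {h: j for j, h in enumerate(self.haplotypes)}
        E = np.zeros((len(self.diplotypes), len(self.haplotypes)))
        for i, dips in enumerate(self.diplotypes):
            for (h1, h2), post in dips:
                E[i, index[h1]] += post
                E[i, index[h2]] += post
        return E

    def map_diplotypes(self) -> list:
        """Maximum-posterior diplotype per dog (hard call)."""
        return [max(dips, key=lambda t: t[1])[0] for dips in self.diplotypes]


def em_haplotype_freqs(genotypes, tol: float = 1e-8, max_iter: int = 500,
                       snp_alleles=None) -> HaplotypeFreqs:
    """EM haplotype frequencies for unphased genotypes over k SNPs (k <= 8).

    ``genotypes`` is dogs x k alt-allele counts; missing data are not
    supported. Iterates from a uniform start until the log-likelihood change
    falls below ``tol``; the log-likelihood is non-decreasing throughout.
    """
    G = np.asarray(genotypes, dtype=int)
    n, k = G.shape
    if k > 8:
        raise ValueError("EM supports at most 8 core SNPs")
    if not np.isin(G, (0, 1, 2)).all():
        raise ValueError("genotypes must be alt-allele counts 0/1/2")

    dog_pairs = [_enumerate_diplotypes(g) for g in G]
    haps = sorted({h for pairs in dog_pairs for pair in pairs for h in pair})
    index = {h: j for j, h in enumerate(haps)}
    H = len(haps)
    freq = np.full(H, 1.0 / H)

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post_all = []
        ll = 0.0
        counts = np.zeros(H)
        for pairs in dog_pairs:
            probs = np.array([
                (2.0 if h1 != h2 else 1.0) * freq[index[h1]] * freq[index[h2]]
                for h1, h2 in pairs
            ])
            tot = probs.sum()
            if tot <= 0:
                probs = np.full(len(pairs), 1.0 / len(pairs))
                tot = 1.0
                ll += -np.inf
            else:
                ll += np.log(tot)
                probs = probs / tot
            post_all.append(probs)
            for (h1, h2), p in zip(pairs, probs):
                counts[index[h1]] += p
                counts[index[h2]] += p
        freq = counts / (2.0 * n)
        if ll - ll_prev < tol and np.isfinite(ll):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll

    diplotypes = [
        [(pair, float(p)) for pair, p in zip(pairs, probs)]
        for pairs, probs in zip(dog_pairs, post_all)
    ]
    return HaplotypeFreqs(
        haplotypes=haps, frequencies=freq, diplotypes=diplotypes,
        log_lik=float(ll_prev), iterations=it, converged=converged,
        snp_alleles=snp_alleles,
    )


@dataclass
class HaplotypeScoreResult:
    haplotypes: list
    frequencies: np.ndarray
    scores: np.ndarray        # signed per-haplotype z statistics
    score_p: np.ndarray
    global_stat: float
    global_df: int
    global_p: float
    dropped: list             # haplotypes excluded (below floor / zero variance)


def haplo_score_test(freqs: HaplotypeFreqs, status, min_freq: float = 0.0,
                     pool_rare: bool = False) -> HaplotypeScoreResult:
    """Global and per-haplotype score tests of haplotype association.

    Haplotypes below ``min_freq`` are skipped (or pooled into one "rare"
    column with ``pool_rare=True``); haplotypes with degenerate score
    variance are dropped and reported.
    """
    y = np.asarray(status, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")
    E = freqs.expected_counts()
    names = list(freqs.haplotypes)
    keep = freqs.frequencies >= min_freq
    dropped = [h for h, k in zip(names, keep) if not k]
    if pool_rare and (~keep).any():
        E = np.column_stack([E[:, keep], E[:, ~keep].sum(axis=1)])
        names = [h for h, k in zip(names, keep) if k] + ["rare"]
        fr = np.append(freqs.frequencies[keep], freqs.frequencies[~keep].sum())
        dropped = []
    else:
        E = E[:, keep]
        names = [h for h, k in zip(names, keep) if k]
        fr = freqs.frequencies[keep]

    n = len(y)
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("status must include both cases and controls")
    Ec = E - E.mean(axis=0)
    U = Ec.T @ (y - ybar)
    V = ybar * (1 - ybar) * (Ec.T @ Ec)

    var = np.diag(V).copy()
    ok = var > 1e-12
    dropped += [h for h, o in zip(names, ok) if not o]
    z = np.full(len(names), np.nan)
    z[ok] = U[ok] / np.sqrt(var[ok])
    p_each = 2.0 * stats.norm.sf(np.abs(z))

    Vk = V[np.ix_(ok, ok)]
    Uk = U[ok]
    Vinv = np.linalg.pinv(Vk)
    gstat = float(Uk @ Vinv @ Uk)
    df = int(np.linalg.matrix_rank(Vk))
    gp = float(stats.chi2(df).sf(gstat)) if df else float("nan")
    return HaplotypeScoreResult(
        haplotypes=names, frequencies=fr, scores=z, score_p=p_each,
        global_stat=gstat, global_df=df, global_p=gp, dropped=dropped,
    )


def haplotype_dosage_model(freqs: HaplotypeFreqs, status, covariates=None,
                           reference_haplotype=None, min_freq: float = 0.05,
                           weighting: str = "map") -> RiskModelFit:
    """Firth-penalized haplotype-dosage model with reference coding.

    Haplotypes with frequency below ``min_freq`` are collapsed into a single
    "rare" term; the a-priori reference haplotype (which must sit above the
    floor) is omitted to avoid collinearity. Per-dog dosages come from the
    maximum-posterior diplotype (``weighting="map"``, hard call, the
    default) or from posterior-expected counts (``weighting="posterior"``).
    """
    ref = tuple(reference_haplotype)
    if ref not in freqs.haplotypes:
        raise ValueError("reference haplotype was never observed")
    if freqs.frequency_of(ref) < min_freq:
        raise ValueError("reference haplotype frequency is below the floor")

    names = list(freqs.haplotypes)
    common = [h for h, f in zip(names, freqs.frequencies) if f >= min_freq]
    rare = [h for h in names if h not in common]

    if weighting == "map":
        D = np.zeros((len(freqs.diplotypes), len(names)))
        index = {h: j for j, h in enumerate(names)}
        for i, (h1, h2) in enumerate(freqs.map_diplotypes()):
            D[i, index[h1]] += 1
            D[i, index[h2]] += 1
    elif weighting == "posterior":
        D = freqs.expected_counts()
    else:
        raise ValueError("weighting must be 'map' or 'posterior'")

    cols, labels = [], []
    for h in common:
        if h == ref:
            continue
        cols.append(D[:, names.index(h)])
        labels.append(freqs.label(h))
    if rare:
        cols.append(D[:, [names.index(h) for h in rare]].sum(axis=1))
        labels.append("rare")
    # constant columns (e.g. a rare pool never assigned under hard calls)
    # carry no information and would make the design singular
    keep = [j for j, c in enumerate(cols) if np.ptp(c) > 0]
    cols = [cols[j] for j in keep]
    labels = [labels[j] for j in keep]
    if not cols:
        raise ValueError("no estimable haplotype terms (all dogs reference)")
    X = np.column_stack([np.ones(D.shape[0])] + cols)
    terms = ["intercept"] + labels
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != X.shape[0]:
            C = C.T
        X = np.column_stack([X, C])
        terms += [f"cov{j + 1}" for j in range(C.shape[1])]
    if np.all(np.ptp(X[:, 1:1 + len(labels)], axis=0) == 0):
        raise ValueError("no estimable haplotype terms (all dogs reference)")
    return firth_logistic(X, np.asarray(status, dtype=float), terms=terms)
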