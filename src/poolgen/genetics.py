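"""Genotype QC and derived genetic exposures.

Covers the genetic side of a multi-study pooled analysis of candidate-gene
case-control data: Hardy-Weinberg equilibrium (HWE) testing among controls,
coding of genotypes under standard inheritance models, haplotype frequency
estimation from unphased genotypes by expectation-maximization (EM), and
per-subject variant burden / classification scores.

Genotypes are coded as copies of the variant allele, ``0``, ``1`` or ``2``,
with ``NaN`` for missing.  Variant sites are named protein changes (e.g.
``R151C``); there is deliberately no VCF reader here because the canonical
variant list is a set of named coding changes, not genomic coordinates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: The nine most frequently studied MC1R coding variants.
CANONICAL_VARIANTS = (
    "V60L", "D84E", "V92M", "R142H", "R151C", "I155T", "R160W", "R163Q", "D294H",
)

__all__ = [
    "CANONICAL_VARIANTS",
    "HweResult",
    "HaplotypeEstimate",
    "VariantClassification",
    "hwe_test",
    "encode_inheritance",
    "em_haplotypes",
    "variant_burden",
]


@dataclass(frozen=True)
class HweResult:
    """Chi-square goodness-of-fit of genotype counts to HWE proportions."""

    n_obs: tuple[int, int, int]
    allele_freq: float
    expected: tuple[float, float, float]
    statistic: float
    df: int
    pvalue: float
    small_expected: bool
    monomorphic: bool = False

    @property
    def n(self) -> int:
        return int(sum(self.n_obs))


def hwe_test(counts) -> HweResult:
    """Test genotype counts ``(n0, n1, n2)`` for departure from HWE.

    Uses the 1-df Pearson chi-square against expected proportions
    ``((1-q)^2, 2q(1-q), q^2)`` with the allele frequency ``q`` estimated
    from the same counts.  A ``small_expected`` flag is raised when any
    expected cell is below 5 (the asymptotic p-value is then unreliable).
    Monomorphic sites return a zero statistic with a warning.

    Parameters
    ----------
    counts
        Genotype counts: homozygous reference, heterozygous, homozygous
        variant.  Intended to be computed among controls, per study.
    """
    n0, n1, n2 = (int(c) for c in counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("at least one genotyped subject required")
    q = (n1 + 2 * n2) / (2 * n)
    expected = (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2)
    if q in (0.0, 1.0):
        warnings.warn("monomorphic site: HWE statistic defined as 0", stacklevel=2)
        return HweResult((n0, n1, n2), q, expected, 0.0, 1, 1.0, True, monomorphic=True)
    stat = sum(
        (o - e) ** 2 / e for o, e in zip((n0, n1, n2), expected) if e > 0
    )
    p = float(stats.chi2.sf(stat, df=1))
    return HweResult(
        (n0, n1, n2), q, expected, float(stat), 1, p,
        small_expected=min(expected) < 5,
    )


def encode_inheritance(copies, model: str):
    """Recode allele copies under an inheritance model.

    ``dominant`` -> carrier indicator; ``recessive`` -> homozygote indicator;
    ``additive`` -> allele count; ``codominant`` -> two indicator columns
    (heterozygote, homozygote).  Missing values propagate as NaN.
    """
    arr = np.asarray(copies, dtype=float)
    bad = arr[~np.isnan(arr)]
    if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype copies must be 0, 1, 2 or missing")
    miss = np.isnan(arr)

    def _mask(x):
        x = x.astype(float)
        x[miss] = np.nan
        return x

    if model == "dominant":
        return _mask(arr >= 1)
    if model == "recessive":
        return _mask(arr == 2)
    if model == "additive":
        return arr.copy()
    if model == "codominant":
        return np.column_stack([_mask(arr == 1), _mask(arr == 2)])
    raise ValueError(f"unknown inheritance model: {model!r}")


@dataclass
class HaplotypeEstimate:
    """EM haplotype frequency estimate over ``L`` biallelic sites.

    ``labels`` are strings over {0,1} per site (``"10"`` carries the variant
    allele at the first site only).  Frequencies sum to one; ``loglik`` is
    the final observed-data log-likelihood.
    """

    labels: tuple[str, ...]
    frequencies: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    n_subjects: int
    loglik_path: np.ndarray = field(repr=False, default=None)


def _haplotype_pairs(geno_row: tuple[int, ...], n_hap: int, L: int):
    """All ordered-unordered haplotype pairs (h1 <= h2) compatible with an
    unphased multi-site genotype, as integer haplotype indices."""
    het_sites = [i for i, g in enumerate(geno_row) if g == 1]
    base = 0
    for i, g in enumerate(geno_row):
        if g == 2:
            base |= 1 << (L - 1 - i)
    pairs = []
    if not het_sites:
        pairs.append((base, base))
        return pairs
    # distribute heterozygous sites between the two haplotypes; fixing the
    # first het site on haplotype 1 halves the enumeration (unordered pairs)
    rest = het_sites[1:]
    first_bit = 1 << (L - 1 - het_sites[0])
    for assign in itertools.product((0, 1), repeat=len(rest)):
        h1, h2 = base | first_bit, base
        for site, a in zip(rest, assign):
            bit = 1 << (L - 1 - site)
            if a:
                h1 |= bit
            else:
                h2 |= bit
        pairs.append((min(h1, h2), max(h1, h2)))
    return pairs


def em_haplotypes(
    genotypes,
    max_iter: int = 5000,
    tol: float = 1e-8,
    restarts: int = 5,
    seed: int = 0,
) -> HaplotypeEstimate:
    """Estimate haplotype frequencies from unphased genotypes by EM.

    Standard EM for diplotype ambiguity: the E-step distributes each
    multi-site heterozygote over its compatible haplotype pairs in
    proportion to the current pair probabilities (``2 f_a f_b`` for
    heterozygous pairs, ``f_a^2`` otherwise); the M-step re-estimates the
    frequency vector from expected haplotype counts.  Subjects with any
    missing genotype at the requested sites are excluded (complete-case).

    The first restart is initialized at linkage equilibrium (the product of
    single-site allele frequencies); further restarts draw Dirichlet(1)
    starts from a seeded generator.  The restart with the best final
    log-likelihood is returned.  Convergence is declared when the largest
    absolute frequency update falls below ``tol``.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.shape[1] == 0:
        raise ValueError("at least one site required")
    complete = ~np.isnan(G).any(axis=1)
    G = G[complete].astype(int)
    n, L = G.shape
    if n == 0:
        raise ValueError("no subjects with complete genotypes at these sites")
    n_hap = 2**L
    labels = tuple(format(h, f"0{L}b") for h in range(n_hap))

    # group identical genotype rows: EM cost then scales with distinct rows
    rows, inverse, counts = np.unique(G, axis=0, return_inverse=True, return_counts=True)
    pair_lists = [_haplotype_pairs(tuple(r), n_hap, L) for r in rows]

    allele_freq = G.mean(axis=0) / 2.0
    rng = np.random.default_rng(seed)

    def _run(f0):
        f = f0.copy()
        path = []
        it = 0
        converged = False
        for it in range(1, max_iter + 1):
            new = np.zeros(n_hap)
            ll = 0.0
            for pairs, w in zip(pair_lists, counts):
                probs = np.array(
                    [f[a] * f[b] * (2.0 if a != b else 1.0) for a, b in pairs]
                )
                tot = probs.sum()
                if tot <= 0:
                    # degenerate start gave this genotype zero mass; restart
                    # from a perturbed point instead of dividing by zero
                    return None
                ll += w * np.log(tot)
                probs /= tot
                for (a, b), pr in zip(pairs, probs):
                    new[a] += w * pr
                    new[b] += w * pr
            new /= 2.0 * n
            path.append(ll)
            if np.max(np.abs(new - f)) < tol:
                f = new
                converged = True
                break
            f = new
        # final log-likelihood at the returned frequencies
        ll = 0.0
        for pairs, w in zip(pair_lists, counts):
            tot = sum(f[a] * f[b] * (2.0 if a != b else 1.0) for a, b in pairs)
            ll += w * np.log(tot)
        path.append(ll)
        return f, ll, it, converged, np.array(path)

    # restart 1: linkage-equilibrium product; others: random Dirichlet
    starts = []
    le = np.ones(n_hap)
    for h in range(n_hap):
        for s in range(L):
            bit = (h >> (L - 1 - s)) & 1
            le[h] *= allele_freq[s] if bit else 1 - allele_freq[s]
    if le.sum() <= 0:  # monomorphic corner: put all mass uniformly
        le = np.ones(n_hap) / n_hap
    starts.append(le / le.sum())
    for _ in range(max(0, restarts - 1)):
        starts.append(rng.dirichlet(np.ones(n_hap)))

    best = None
    for f0 in starts:
        out = _run(f0)
        if out is None:
            continue
        if best is None or out[1] > best[1] + 1e-12:
            best = out
    if best is None:  # pragma: no cover - all starts degenerate
        raise RuntimeError("EM failed from every start")
    f, ll, it, conv, path = best
    f = np.clip(f, 0.0, None)
    f /= f.sum()
    return HaplotypeEstimate(labels, f, float(ll), it, conv, n, path)


@dataclass
class VariantClassification:
    """User-supplied mapping of variant sites to functional classes.

    The class semantics (e.g. strong "R" vs weak "r" red-hair-colour
    alleles) are configurable, not fixed by this package: pass
    ``classes={"R151C": "R", "V60L": "r", ...}``.  Sites absent from the
    map are reported as unclassified and excluded from class scores but
    still count toward the total allele burden.
    """

    classes: dict[str, str]

    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.classes.values())))


def variant_burden(genotypes: pd.DataFrame, classification: VariantClassification | None = None):
    """Per-subject total variant-allele count and per-class allele scores.

    ``genotypes`` is a subjects x sites frame of allele copies.  Missing
    genotypes are ignored in the sums (treated as contributing 0 copies);
    callers wanting strict complete-case behaviour should filter first.

    Returns a DataFrame with a ``burden`` column and one ``score_<class>``
    column per classification label.
    """
    G = genotypes.astype(float)
    out = pd.DataFrame(index=G.index)
    out["burden"] = G.fillna(0.0).sum(axis=1)
    if classification is not None:
        for label in classification.labels():
            sites = [s for s, c in classification.classes.items() if c == label and s in G.columns]
            out[f"score_{label}"] = G[sites].fillna(0.0).sum(axis=1) if sites else 0.0
        unclassified = [c for c in G.columns if c not in classification.classes]
        out.attrs["unclassified_sites"] = tuple(unclassified)
    return out
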