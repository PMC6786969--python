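"""Synonymous-distance (Ks) estimation and Gaussian mixture decomposition.

Ks — synonymous substitutions per synonymous site — accumulates roughly
clock-like, so the Ks values of duplicate gene pairs cluster around the age
of the event that created them: a whole-genome duplication leaves a peak,
and the orthologue Ks distribution between two genomes peaks at their
divergence.  The module estimates Ks per codon-aligned pair with the
Nei-Gojobori (1986) counting method (equal-weight pathway averaging,
Jukes-Cantor multiple-hit correction), applies the 0.05-5 usable range
filter, and decomposes a Ks sample into univariate Gaussian components by
expectation-maximisation, selecting the number of components (up to nine)
with the Bayesian information criterion.

Externally computed Ks tables (e.g. codeml output) can be loaded with
:func:`read_ks_table` and fed to the same mixture machinery.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignmentPair",
    "KsPair",
    "MixtureFit",
    "ks_ng86",
    "filter_ks",
    "fit_mixture",
    "select_model",
    "read_ks_table",
    "write_ks_table",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


class KsError(ValueError):
    """Invalid codon pair input."""


@dataclass(frozen=True)
class CodonAlignmentPair:
    """A gap-free, in-frame pair of aligned coding sequences."""

    seq_a: str
    seq_b: str

    def __post_init__(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise KsError("sequences differ in length")
        if len(a) % 3 != 0:
            raise KsError("length not divisible by 3")
        if set(a + b) - set(_BASES):
            raise KsError("non-ACGT characters (strip gaps and ambiguity codes first)")
        for seq in (a, b):
            for i in range(0, len(seq), 3):
                if seq[i:i + 3] in _STOPS:
                    raise KsError(f"internal stop codon at position {i}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3


@dataclass(frozen=True)
class KsPair:
    gene_a: str
    gene_b: str
    ks: Optional[float]  # None when saturated/uncomputable
    ka: Optional[float] = None
    relationship: str = "unclassified"  # syntenic_paralogue | syntenic_orthologue | tandem | unclassified


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986)


def _site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site fractions of one codon (sum to 3).

    Mutations to stop codons count as nonsynonymous, matching the common
    convention.
    """
    syn = 0
    aa = _AA[codon]
    for i in range(3):
        for base in _BASES:
            if base == codon[i]:
                continue
            alt = codon[:i] + base + codon[i + 1:]
            if alt not in _STOPS and _AA[alt] == aa:
                syn += 1
    s = syn / 3.0
    return s, 3.0 - s


def _step_class(c1: str, c2: str) -> str:
    """'syn' or 'nonsyn' for two codons one nucleotide apart."""
    if c2 in _STOPS or c1 in _STOPS:
        return "nonsyn"
    return "syn" if _AA[c1] == _AA[c2] else "nonsyn"


def _diff_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons.

    All minimal mutational pathways are weighted equally; pathways passing
    through a stop codon are excluded (unless every pathway does).
    """
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    path_counts = []
    blocked = []
    for order in itertools.permutations(positions):
        current = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if _step_class(current, nxt) == "syn":
                syn += 1
            else:
                nonsyn += 1
            if nxt in _STOPS:
                through_stop = True
            current = nxt
        (blocked if through_stop else path_counts).append((syn, nonsyn))
    if not path_counts:
        path_counts = blocked
    syn = sum(p[0] for p in path_counts) / len(path_counts)
    nonsyn = sum(p[1] for p in path_counts) / len(path_counts)
    return syn, nonsyn


def _jukes_cantor(p: float) -> Optional[float]:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


def ks_ng86(pair: CodonAlignmentPair) -> tuple[Optional[float], Optional[float]]:
    """(ks, ka) for one codon-aligned pair; None marks saturation.

    Sites are averaged between the two sequences; multiple hits are corrected
    with the Jukes-Cantor formula.  A warning is emitted below 30 codons,
    where counting estimates are noisy.
    """
    if pair.n_codons < 30:
        import warnings

        warnings.warn(f"only {pair.n_codons} codons; Ks estimate will be noisy")
    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    for i in range(0, len(pair.seq_a), 3):
        ca, cb = pair.seq_a[i:i + 3], pair.seq_b[i:i + 3]
        sa, na = _site_counts(ca)
        sb, nb = _site_counts(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        sd, nd = _diff_counts(ca, cb)
        s_diff += sd
        n_diff += nd
    ks = _jukes_cantor(s_diff / s_sites) if s_sites > 0 else None
    ka = _jukes_cantor(n_diff / n_sites) if n_sites > 0 else None
    return ks, ka


# ---------------------------------------------------------------------------
# Range filter


@dataclass(frozen=True)
class FilterReport:
    kept: list
    n_below: int
    n_above: int
    n_undefined: int


def filter_ks(pairs: Iterable[KsPair], lo: float = 0.05, hi: float = 5.0) -> FilterReport:
    """Keep pairs with lo <= ks <= hi (both endpoints included)."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    kept, n_below, n_above, n_undef = [], 0, 0, 0
    for p in pairs:
        if p.ks is None or math.isnan(p.ks):
            n_undef += 1
        elif p.ks < lo:
            n_below += 1
        elif p.ks > hi:
            n_above += 1
        else:
            kept.append(p)
    return FilterReport(kept, n_below, n_above, n_undef)


# ---------------------------------------------------------------------------
# Gaussian mixture by EM


@dataclass(frozen=True)
class MixtureFit:
    """A fitted K-component univariate Gaussian mixture.

    Components are ordered by ascending mean.  ``bic`` uses the parameter
    count 3K-1 (K means, K variances, K-1 free weights).
    """

    k: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    loglik: float
    bic: float
    n: int
    hard_counts: np.ndarray  # pairs per component by maximum responsibility
    soft_counts: np.ndarray  # responsibility-weighted pair counts
    n_iter: int
    bic_table: Optional[pd.DataFrame] = None

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[:, None]
        comp = self.weights * _normal_pdf(x, self.means, self.variances)
        return comp.sum(axis=1)


def _normal_pdf(x, mean, var):
    return np.exp(-0.5 * (x - mean) ** 2 / var) / np.sqrt(2.0 * math.pi * var)


def _log_mixture(x: np.ndarray, means, variances, weights) -> tuple[np.ndarray, float]:
    """Per-point log responsibilities (unnormalized) and total log-likelihood."""
    log_comp = (
        np.log(weights)
        - 0.5 * np.log(2.0 * math.pi * variances)
        - 0.5 * (x[:, None] - means) ** 2 / variances
    )
    m = log_comp.max(axis=1, keepdims=True)
    log_norm = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
    return log_comp - log_norm[:, None], float(log_norm.sum())


def _kmeans_init(x: np.ndarray, k: int, rng: np.random.Generator,
                 jitter: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic k-means-style starting point.

    The first start uses exact quantile means; subsequent ones perturb with
    the seeded generator, then run a few Lloyd iterations.
    """
    qs = (np.arange(k) + 0.5) / k
    means = np.quantile(x, qs)
    if jitter:
        means = rng.choice(x, size=k, replace=False) if len(x) >= k else means
        means = np.sort(means)
    for _ in range(10):
        assign = np.argmin(np.abs(x[:, None] - means), axis=1)
        for j in range(k):
            sel = x[assign == j]
            if len(sel):
                means[j] = sel.mean()
    assign = np.argmin(np.abs(x[:, None] - means), axis=1)
    variances = np.empty(k)
    weights = np.empty(k)
    global_var = max(x.var(), 1e-6)
    for j in range(k):
        sel = x[assign == j]
        weights[j] = max(len(sel), 1) / len(x)
        variances[j] = sel.var() if len(sel) > 1 and sel.var() > 1e-8 else global_var / k
    weights /= weights.sum()
    return means, variances, weights


def _em(x, means, variances, weights, tol, max_iter):
    """One EM run; returns (params, loglik, n_iter, trace) or None on collapse.

    Densities are computed directly (no log-sum-exp): with the 1e-8 variance
    floor the per-component log-density is bounded above by ~9, so overflow
    is impossible, and a point underflowing in every component only occurs
    mid-collapse, which is treated as such.  The M-step uses matrix products
    with data centred at the sample mean, keeping the E[x^2]-mean^2 variance
    form accurate far above the collapse floor.
    """
    n = len(x)
    centre = x.mean()
    xc = x - centre
    xc2 = xc * xc
    means = means - centre
    prev = -math.inf
    trace = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        amp = weights / np.sqrt(2.0 * math.pi * variances)
        comp = amp * np.exp((xc[:, None] - means) ** 2 / (-2.0 * variances))
        tot = comp.sum(axis=1)
        if not np.all(tot > 0.0):
            return None
        loglik = float(np.log(tot).sum())
        trace.append(loglik)
        resp = comp / tot[:, None]
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-12):
            return None
        weights = nk / n
        means = (resp.T @ xc) / nk
        variances = (resp.T @ xc2) / nk - means * means
        if np.any(variances < 1e-8):
            return None
        if loglik - prev < tol and n_iter > 1:
            break
        prev = loglik
    _, loglik = _log_mixture(x, means + centre, variances, weights)
    trace.append(loglik)
    return (means + centre, variances, weights), loglik, n_iter, trace


def fit_mixture(
    values: Sequence[float],
    k: int,
    seed: Optional[int] = None,
    n_init: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_short_iter: int = 50,
) -> MixtureFit:
    """EM fit of a K-component unequal-variance Gaussian mixture.

    Each of ``n_init`` deterministic k-means-style initialisations (from
    ``seed``) is advanced by a short EM run (``n_short_iter`` iterations);
    the most promising one is then run to convergence (log-likelihood
    improvement below ``tol`` or ``max_iter`` iterations).  The
    log-likelihood is non-decreasing across EM iterations (the trace is kept
    on the result as ``loglik_trace``).  Component collapse (variance below
    1e-8) triggers re-initialisation; after 10 consecutive failures an error
    is raised.
    """
    x = np.asarray(values, dtype=float)
    if len(x) <= 3 * k:
        raise ValueError(f"need more than {3 * k} points for K={k}")
    rng = np.random.default_rng(seed)
    candidates = []
    failures = 0
    attempts = 0
    while attempts < n_init:
        means, variances, weights = _kmeans_init(x, k, rng, jitter=attempts > 0)
        out = _em(x, means, variances, weights, tol, min(n_short_iter, max_iter))
        if out is None:
            failures += 1
            if failures >= 10:
                raise RuntimeError(f"EM collapsed 10 times for K={k}")
            continue
        attempts += 1
        candidates.append(out)
    # polish the most promising starts to full convergence; a start that
    # collapses when run longer is discarded in favour of the next one
    candidates.sort(key=lambda c: -c[1])
    polished = None
    for (means, variances, weights), _, n_short, trace_short in candidates:
        out = _em(x, means, variances, weights, tol, max_iter)
        if out is not None:
            polished = (out, n_short, trace_short)
            break
    if polished is None:
        raise RuntimeError(f"EM collapsed in every polish attempt for K={k}")
    ((means, variances, weights), loglik, n_iter, trace), n_short, trace_short = polished
    n_iter += n_short
    trace = trace_short + trace
    order = np.argsort(means)
    means, variances, weights = means[order], variances[order], weights[order]
    log_resp, _ = _log_mixture(x, means, variances, weights)
    resp = np.exp(log_resp)
    hard = np.bincount(resp.argmax(axis=1), minlength=k)
    n = len(x)
    bic = -2.0 * loglik + (3 * k - 1) * math.log(n)
    fit = MixtureFit(
        k=k, means=means, variances=variances, weights=weights,
        loglik=loglik, bic=bic, n=n,
        hard_counts=hard, soft_counts=resp.sum(axis=0), n_iter=n_iter,
    )
    object.__setattr__(fit, "loglik_trace", trace)
    return fit


def select_model(
    values: Sequence[float],
    k_max: int = 9,
    seed: Optional[int] = None,
    **kwargs,
) -> MixtureFit:
    """Fit K = 1..k_max and return the fit minimising BIC.

    The full BIC table is attached to the returned fit (``bic_table``).
    Components for which n <= 3K would be violated are not attempted.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    fits = []
    rows = []
    for k in range(1, k_max + 1):
        if len(values) <= 3 * k:
            break
        fit = fit_mixture(values, k, seed=seed, **kwargs)
        fits.append(fit)
        rows.append({"K": k, "loglik": fit.loglik, "bic": fit.bic})
    best = min(fits, key=lambda f: f.bic)
    table = pd.DataFrame(rows)
    return MixtureFit(
        k=best.k, means=best.means, variances=best.variances,
        weights=best.weights, loglik=best.loglik, bic=best.bic, n=best.n,
        hard_counts=best.hard_counts, soft_counts=best.soft_counts,
        n_iter=best.n_iter, bic_table=table,
    )


# ---------------------------------------------------------------------------
# Ks table I/O


def write_ks_table(pairs: Iterable[KsPair], path) -> None:
    df = pd.DataFrame(
        [{"gene_a": p.gene_a, "gene_b": p.gene_b,
          "ks": "" if p.ks is None else p.ks,
          "ka": "" if p.ka is None else p.ka,
          "class": p.relationship} for p in pairs]
    )
    df.to_csv(path, sep="\t", index=False)


def read_ks_table(path) -> list[KsPair]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        ks = row.get("ks")
        ks = None if pd.isna(ks) else float(ks)
        ka = row.get("ka")
        ka = None if (ka is None or pd.isna(ka)) else float(ka)
        out.append(KsPair(str(row["gene_a"]), str(row["gene_b"]), ks, ka,
                          str(row.get("class", "unclassified"))))
    return out
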