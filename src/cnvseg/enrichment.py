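"""Over-representation statistics and kappa-based annotation clustering.

The enrichment statistic is the exact hypergeometric upper tail
P(X >= k) for drawing k members of a K-sized term when sampling n
features from a universe of N, evaluated in log space for numerical
safety at any scale.  An optional EASE-style variant (one overlap member
removed, the conservative jackknife used by popular annotation servers)
sits behind a flag.

Terms are grouped by single-linkage clustering on Cohen's kappa between
their membership vectors; each surviving cluster is represented by its
lowest-p term, and clusters whose best p-value is not below 0.05 are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TermSet",
    "EnrichmentRecord",
    "AnnotationCluster",
    "hypergeom_upper_tail",
    "term_enrichment",
    "kappa_similarity",
    "cluster_annotations",
    "read_gmt",
]


@dataclass(frozen=True)
class TermSet:
    term_id: str
    term_name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id} has no members")


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    adjusted_p: float | None = None


@dataclass(frozen=True)
class AnnotationCluster:
    member_term_ids: tuple
    representative_term_id: str
    enrichment_score: float


_LOGFACT = np.array([0.0])


def _logfact(n: int) -> np.ndarray:
    """Cached log-factorial table 0..n (grown on demand)."""
    global _LOGFACT
    if len(_LOGFACT) <= n:
        _LOGFACT = gammaln(np.arange(max(n + 1, 2 * len(_LOGFACT))) + 1.0)
    return _LOGFACT


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    Sums C(K, j) * C(N-K, n-j) / C(N, n) over j = k..min(K, n) via a
    log-factorial table and logsumexp.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent parameters K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min({K}, {n})]")
    lf = _logfact(N)
    jmin = max(k, n - (N - K))  # support lower bound
    jmax = min(K, n)
    if jmin > jmax:
        return 1.0  # k below the support: the whole mass is in the tail
    j = np.arange(jmin, jmax + 1)
    log_terms = (
        lf[K] - lf[j] - lf[K - j]
        + lf[N - K] - lf[n - j] - lf[N - K - (n - j)]
        - (lf[N] - lf[n] - lf[N - n])
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def term_enrichment(
    query,
    universe,
    terms: list[TermSet],
    adjust: bool = True,
    ease: bool = False,
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of each term in the query set.

    ``ease`` removes one overlap member before computing the tail (the
    conservative EASE variant).  Records are sorted ascending by p-value
    (ties by term id); Benjamini-Hochberg adjusted p-values are attached
    when ``adjust`` is on.
    """
    query = frozenset(query)
    universe = frozenset(universe)
    if not query:
        raise ValueError("query set is empty")
    if not query <= universe:
        raise ValueError(
            f"query not contained in universe ({sorted(query - universe)[:5]} ...)"
        )
    N, n = len(universe), len(query)
    records = []
    for t in terms:
        members = t.members & universe
        if not members:
            continue
        K = len(members)
        k = len(members & query)
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(k_eff, K, n, N)
        records.append(EnrichmentRecord(t.term_id, k, K, n, N, p))
    if adjust and records:
        _, adj, *_ = multipletests([r.p_value for r in records], method="fdr_bh")
        records = [
            EnrichmentRecord(r.term_id, r.k, r.K, r.n, r.N, r.p_value, float(a))
            for r, a in zip(records, adj)
        ]
    return sorted(records, key=lambda r: (r.p_value, r.term_id))


def kappa_similarity(membership_a, membership_b) -> float:
    """Cohen's kappa between two binary membership vectors.

    Defined as 1.0 when the vectors are identical and chance agreement is
    total (both constant), keeping the similarity well-defined for
    degenerate terms.
    """
    a = np.asarray(membership_a, dtype=bool)
    b = np.asarray(membership_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("membership vectors must be equal-length 1-D, length >= 1")
    n = len(a)
    o11 = np.count_nonzero(a & b)
    o00 = np.count_nonzero(~a & ~b)
    po = (o11 + o00) / n
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float((po - pe) / (1 - pe))


def cluster_annotations(
    records: list[EnrichmentRecord],
    memberships: dict,
    kappa_threshold: float = 0.5,
    p_cutoff: float = 0.05,
    universe=None,
) -> list[AnnotationCluster]:
    """Single-linkage kappa clustering with a lowest-p representative.

    ``memberships`` maps term_id -> set of feature names; membership
    vectors are formed over ``universe`` (default: the union of all member
    sets).  Terms whose pairwise kappa reaches ``kappa_threshold`` end up
    in one cluster (single linkage = connected components at the
    threshold).  Clusters whose best p-value is not below ``p_cutoff`` are
    discarded; the representative is the minimum-p member, ties broken
    lexicographically by term id.  The enrichment score is the negative
    mean log10 p of the members.
    """
    recs = sorted(records, key=lambda r: r.term_id)
    term_ids = [r.term_id for r in recs]
    missing = [t for t in term_ids if t not in memberships]
    if missing:
        raise ValueError(f"no membership vectors for terms {missing[:5]}")
    if universe is None:
        universe = set().union(*(memberships[t] for t in term_ids)) if term_ids else set()
    feats = sorted(universe)
    fidx = {f: i for i, f in enumerate(feats)}
    vecs = {}
    for t in term_ids:
        v = np.zeros(len(feats), dtype=bool)
        for f in memberships[t]:
            if f in fidx:
                v[fidx[f]] = True
        vecs[t] = v

    parent = {t: t for t in term_ids}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, a in enumerate(term_ids):
        for b in term_ids[i + 1 :]:
            if kappa_similarity(vecs[a], vecs[b]) >= kappa_threshold:
                parent[find(a)] = find(b)

    groups: dict[str, list[EnrichmentRecord]] = {}
    for r in recs:
        groups.setdefault(find(r.term_id), []).append(r)

    clusters = []
    for members in groups.values():
        best = min(members, key=lambda r: (r.p_value, r.term_id))
        if not best.p_value < p_cutoff:
            continue
        score = float(-np.mean([np.log10(r.p_value) for r in members]))
        clusters.append(
            AnnotationCluster(
                member_term_ids=tuple(sorted(r.term_id for r in members)),
                representative_term_id=best.term_id,
                enrichment_score=score,
            )
        )
    return sorted(clusters, key=lambda c: (-c.enrichment_score, c.representative_term_id))


def read_gmt(path) -> list[TermSet]:
    """Read a GMT-like term file: term_id <tab> term_name <tab> members..."""
    terms = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = [f for f in line.split("\t")]
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: need id, name and >= 1 member")
            terms.append(
                TermSet(fields[0], fields[1], frozenset(f for f in fields[2:] if f))
            )
    return terms
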