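"""Fragment-based average nucleotide identity and species delimitation.

The query genome is cut into consecutive fixed-length fragments (default
1000 bp); each fragment's best local hit on the subject contributes its
identity, and ANI is the mean over fragments with a retained hit. This is
the fragment-decomposition style of ANI estimation; MUMmer-based variants
are not reproduced bit-for-bit — what matters here is parameter recovery
over the divergence regimes simulated (within-species ~1%, between-species
>15%). A fragment's hit is retained only if it aligns over at least
``min_fragment_aligned`` columns, which keeps chance word matches between
unrelated genomes from contributing spuriously perfect short fragments.

ANI is direction-dependent; clustering uses the symmetrized mean of the two
directions. Species are delimited by single-linkage clustering of the ANI
distance (1 - ANI) cut strictly below 5%, the operational species boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import ReferenceIndex, best_hit, find_local_hits


@dataclass
class ANIResult:
    query_id: str
    subject_id: str
    ani: float | None  # None when no fragment aligned
    aligned_fraction: float
    n_fragments_aligned: int


def ani_pairwise(query: str, subject, fragment_length: int = 1000,
                 min_fragment_identity: float = 0.30,
                 min_fragment_aligned: int = 200,
                 query_id: str = "query", subject_id: str = "subject",
                 word_size: int = 9) -> ANIResult:
    """ANI of query against subject by best-hit fragment decomposition.

    ``subject`` may be a sequence or a pre-built
    :class:`~paleostrain.alignment.ReferenceIndex` (reused across queries).
    """
    if isinstance(subject, str):
        if len(query) < fragment_length or len(subject) < fragment_length:
            raise ValueError("both sequences must be >= fragment_length")
        subject = ReferenceIndex(subject, word_size)
    identities = []
    n_frags = len(query) // fragment_length
    aligned_bases = 0
    for k in range(n_frags):
        frag = query[k * fragment_length:(k + 1) * fragment_length]
        hit = best_hit(find_local_hits(frag, subject, word_size=word_size))
        if hit is None or hit.length < min_fragment_aligned \
                or hit.identity < min_fragment_identity:
            continue
        identities.append(hit.identity)
        aligned_bases += fragment_length
    if not identities:
        return ANIResult(query_id, subject_id, None, 0.0, 0)
    return ANIResult(query_id, subject_id, float(np.mean(identities)),
                     aligned_bases / (n_frags * fragment_length),
                     len(identities))


@dataclass
class ANIMatrix:
    """All ordered-pair ANI results with a symmetrized distance summary."""

    ids: list[str]
    results: dict[tuple[str, str], ANIResult]

    def distance_frame(self) -> pd.DataFrame:
        """Symmetrized ANI distance: 1 - mean(ani(a,b), ani(b,a));
        NaN where neither direction aligned."""
        n = len(self.ids)
        d = pd.DataFrame(np.zeros((n, n)), index=self.ids, columns=self.ids)
        for i, a in enumerate(self.ids):
            for j, b in enumerate(self.ids):
                if i >= j:
                    continue
                anis = [r.ani for r in (self.results[(a, b)], self.results[(b, a)])
                        if r.ani is not None]
                val = 1.0 - float(np.mean(anis)) if anis else np.nan
                d.loc[a, b] = d.loc[b, a] = val
        return d


def ani_matrix(genomes: dict[str, str], fragment_length: int = 1000,
               min_fragment_identity: float = 0.30,
               min_fragment_aligned: int = 200,
               word_size: int = 9) -> ANIMatrix:
    """Compute ANI for all ordered pairs (each subject indexed once)."""
    ids = list(genomes)
    indexes = {g: ReferenceIndex(genomes[g], word_size) for g in ids}
    results = {}
    for a in ids:
        for b in ids:
            if a == b:
                results[(a, b)] = ANIResult(a, b, 1.0, 1.0,
                                            len(genomes[a]) // fragment_length)
                continue
            results[(a, b)] = ani_pairwise(
                genomes[a], indexes[b], fragment_length,
                min_fragment_identity, min_fragment_aligned,
                query_id=a, subject_id=b, word_size=word_size)
    return ANIMatrix(ids, results)


def delimit_species(matrix: ANIMatrix | pd.DataFrame,
                    max_intra_distance: float = 0.05) -> list[set[str]]:
    """Single-linkage species clusters cut strictly below the threshold.

    Pairs at distance exactly max_intra_distance are NOT merged. Genomes
    with all pairwise distances undefined become singletons. Clusters are
    returned sorted by their smallest member id.
    """
    d = matrix.distance_frame() if isinstance(matrix, ANIMatrix) else matrix
    ids = list(d.index)
    parent = {g: g for g in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            val = d.loc[a, b]
            if not np.isnan(val) and val < max_intra_distance:
                parent[find(a)] = find(b)
    clusters: dict[str, set[str]] = {}
    for g in ids:
        clusters.setdefault(find(g), set()).add(g)
    return sorted(clusters.values(), key=lambda s: min(s))
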