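"""Bundled worked example: clonal structure of nine *Pocillopora acuta*
populations surveyed along ~50 km of reef around Phuket Island
(Andaman Sea), scored at six microsatellite loci.

What is bundled is the published per-population clonal partition — the
sample size N, the number of multilocus genotypes N_MLG and the clone
group sizes (how many colonies share each MLG) — which is all the
clonality statistics need.  ``worked_example_stats`` recomputes the
summary table from these group sizes; ``worked_example_matrix`` builds
a synthetic genotype matrix realising the same partition (distinct
six-locus genotypes per MLG, replicated per clone member) so the
end-to-end path matrix -> MLG assignment -> statistics can be
exercised on it.
"""

from __future__ import annotations

import numpy as np

from .clonality import ClonalStats, clonal_stats_from_sizes
from .genotype_io import GenotypeMatrix, LocusMeta

__all__ = [
    "CLONE_GROUP_SIZES",
    "SITE_NAMES",
    "worked_example_stats",
    "worked_example_matrix",
]

# Clone group sizes per population: k * [1] means k singleton genotypes;
# larger entries are MLGs shared by that many colonies.
CLONE_GROUP_SIZES: dict[str, list[int]] = {
    "KA": [1] * 7 + [2] * 3,
    "KNA": [1] * 14,
    "KNO": [1] * 11,
    "KR": [1] * 19 + [3],
    "LP": [1] * 14 + [4],
    "PN": [1] * 19,
    "PS": [1] * 13,
    "PW": [1] * 48 + [3],
    "TK": [1] * 41 + [2] * 4 + [3, 4],
}

SITE_NAMES: dict[str, str] = {
    "KA": "Kamala",
    "KNA": "Khai Nai",
    "KNO": "Khai Nok",
    "KR": "Koh Nung Krabi",
    "LP": "Li Pe",
    "PN": "Patong North",
    "PS": "Patong South",
    "PW": "Panwa",
    "TK": "Tang Khem",
}


def worked_example_stats() -> dict[str, ClonalStats]:
    """Per-population clonal statistics of the worked example."""
    return {
        pop: clonal_stats_from_sizes(sizes, population=pop)
        for pop, sizes in CLONE_GROUP_SIZES.items()
    }


def worked_example_matrix(n_loci: int = 6, seed: int = 0) -> GenotypeMatrix:
    """Synthetic genotype matrix realising the worked-example partition.

    Every MLG receives a distinct randomly drawn ``n_loci``-locus
    genotype (allele sizes on a dinucleotide ladder); clone members
    repeat their MLG's genotype exactly.  Only the partition is real;
    the allele calls are synthetic placeholders.
    """
    rng = np.random.default_rng(seed)
    individuals: list[str] = []
    populations: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[bytes] = set()
    for pop, sizes in CLONE_GROUP_SIZES.items():
        for g, size in enumerate(sizes):
            while True:
                geno = np.sort(
                    100 + 2 * rng.integers(0, 30, size=(n_loci, 2)), axis=1
                )
                key = geno.tobytes()
                if key not in seen:
                    seen.add(key)
                    break
            for m in range(size):
                individuals.append(f"{pop}_{g + 1:02d}_{m + 1}")
                populations.append(pop)
                rows.append(geno)
    return GenotypeMatrix(
        individuals=individuals,
        populations=populations,
        loci=[LocusMeta(name=f"L{j + 1}", motif_length=2) for j in range(n_loci)],
        calls=np.stack(rows),
    )
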