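"""Forward simulation of multi-deme diploid microsatellite datasets.

The generator produces data with a known truth layer so that every
downstream estimator (clone detection, FST, admixture clustering,
isolation by distance) can be validated without field data.  Deme
allele frequencies follow an F-model: ancestral frequencies are drawn
from a flat-ish Dirichlet and each deme's frequencies from
``Dirichlet(p_ancestral * (1 - F) / F)``, which has expected
Weir-Cockerham FST equal to ``target_F``.  Clonality is injected by
replacing a fraction ``c`` of each deme with copies (ramets) of
uniformly chosen founders, optionally perturbed by one-step stepwise
mutations; null alleles and missing data corrupt the observed calls
after the truth is recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .genotype_io import GenotypeMatrix, LocusMeta

__all__ = ["SimConfig", "SimulatedDataset", "sample_deme_frequencies", "simulate_dataset"]


@dataclass
class SimConfig:
    """Configuration for one simulated dataset.

    Defaults emulate a mid-size microsatellite survey: a handful of
    demes of 15-60 colonies scored at six loci with moderate allelic
    richness, moderate differentiation and no clonality unless asked.
    """

    n_demes: int = 3
    deme_sizes: tuple[int, ...] | int = 30
    n_loci: int = 6
    alleles_per_locus: int = 8
    ancestral_freq_concentration: float = 1.0
    target_F: float = 0.1
    spatial_mode: Literal["island", "stepping_stone"] = "island"
    clonality_c: float = 0.0
    somatic_step_prob: float = 0.0
    missing_rate: float = 0.0
    null_allele_freq: float = 0.0
    null_allele_locus: int = 0
    motif_length: int = 2
    base_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.deme_sizes, int):
            self.deme_sizes = (self.deme_sizes,) * self.n_demes
        self.deme_sizes = tuple(int(s) for s in self.deme_sizes)
        if len(self.deme_sizes) != self.n_demes:
            raise ValueError("deme_sizes length must equal n_demes")
        if any(s < 2 for s in self.deme_sizes):
            raise ValueError("deme_sizes must all be >= 2")
        if not 0.0 <= self.target_F < 1.0:
            raise ValueError("target_F must be in [0, 1)")
        for name in ("clonality_c", "somatic_step_prob", "missing_rate", "null_allele_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.spatial_mode not in ("island", "stepping_stone"):
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulatedDataset:
    """A genotype matrix plus the truth that generated it."""

    genotypes: GenotypeMatrix
    is_clone: np.ndarray          # bool per individual: a copy of a founder?
    parent: np.ndarray            # int per individual: index of the copied founder (-1 for founders)
    deme_frequencies: np.ndarray  # (n_demes, n_loci, n_alleles) sampling frequencies
    allele_sizes: np.ndarray      # (n_loci, n_alleles) fragment size of each allele index
    config: SimConfig = field(repr=False, default=None)

    @property
    def n_founders(self) -> int:
        return int((~self.is_clone).sum())

    def truth_to_json(self, path: str | Path) -> None:
        obj = {
            "is_clone": self.is_clone.astype(int).tolist(),
            "parent": self.parent.tolist(),
            "individuals": self.genotypes.individuals,
            "populations": self.genotypes.populations,
        }
        Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def _stepping_stone_step_f(target: float, n_demes: int) -> float:
    """Per-step drift F so mean differentiation over demes hits the target.

    Deme i sits i drift steps from the ancestor; after k steps the
    expected divergence is 1 - (1 - f)^k.  Solve for f so the mean over
    demes equals ``target``.
    """
    if target == 0.0:
        return 0.0

    def mean_f(f: float) -> float:
        ks = np.arange(1, n_demes + 1)
        return float(np.mean(1.0 - (1.0 - f) ** ks)) - target

    return brentq(mean_f, 1e-12, 1.0 - 1e-12)


def sample_deme_frequencies(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-deme per-locus allele frequencies under the F-model.

    Returns an array of shape (n_demes, n_loci, alleles_per_locus).
    ``target_F = 0`` degenerates to every deme sharing the ancestral
    frequencies exactly.  In ``stepping_stone`` mode demes drift
    sequentially along a line so divergence grows with deme distance.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    A, L, D = config.alleles_per_locus, config.n_loci, config.n_demes
    anc = rng.dirichlet([config.ancestral_freq_concentration] * A, size=L)  # (L, A)
    if config.target_F == 0.0:
        return np.broadcast_to(anc, (D, L, A)).copy()

    freqs = np.empty((D, L, A))
    if config.spatial_mode == "island":
        scale = (1.0 - config.target_F) / config.target_F
        for d in range(D):
            for l in range(L):
                alpha = np.maximum(anc[l] * scale, 1e-9)
                freqs[d, l] = rng.dirichlet(alpha)
    else:  # stepping_stone: serial drift along a line
        f_step = _stepping_stone_step_f(config.target_F, D)
        scale = (1.0 - f_step) / f_step
        prev = anc
        for d in range(D):
            cur = np.empty_like(prev)
            for l in range(L):
                alpha = np.maximum(prev[l] * scale, 1e-9)
                cur[l] = rng.dirichlet(alpha)
            freqs[d] = cur
            prev = cur
    return freqs


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Simulate one dataset under ``config``.

    Within each deme, ``ceil((1 - c) * n)`` founders are independent
    Hardy-Weinberg draws from the deme frequencies; the remaining
    individuals copy a uniformly chosen founder of the same deme, after
    which each locus of a copy shifts by one motif step (up or down)
    with probability ``somatic_step_prob``.  Null-allele carriers at the
    designated locus appear homozygous for their visible allele; null
    homozygotes become MISSING.  Independent missingness is applied
    last.  The truth (clone flags, parent ids, sampling frequencies)
    reflects the uncorrupted state.
    """
    rng = np.random.default_rng(config.seed)
    freqs = sample_deme_frequencies(config, rng)
    A, L = config.alleles_per_locus, config.n_loci
    sizes = config.base_size + config.motif_length * np.arange(A)  # shared ladder
    allele_sizes = np.broadcast_to(sizes, (L, A)).copy()

    individuals: list[str] = []
    populations: list[str] = []
    calls_idx: list[np.ndarray] = []   # per-individual (L, 2) allele *indices*, -1 impossible
    is_clone: list[bool] = []
    parent: list[int] = []

    offset = 0
    for d in range(config.n_demes):
        n = config.deme_sizes[d]
        n_found = int(np.ceil((1.0 - config.clonality_c) * n))
        n_found = max(1, min(n, n_found))
        # founders: HW draws of two allele indices per locus
        founders = np.empty((n_found, L, 2), dtype=np.int64)
        for l in range(L):
            founders[:, l, :] = rng.choice(A, size=(n_found, 2), p=freqs[d, l])
        deme_calls = [founders[i] for i in range(n_found)]
        deme_clone = [False] * n_found
        deme_parent = [-1] * n_found
        for _ in range(n - n_found):
            src = int(rng.integers(n_found))
            g = founders[src].copy()
            if config.somatic_step_prob > 0.0:
                for l in range(L):
                    if rng.random() < config.somatic_step_prob:
                        which = int(rng.integers(2))
                        step = 1 if rng.random() < 0.5 else -1
                        g[l, which] = int(np.clip(g[l, which] + step, 0, A - 1))
            deme_calls.append(g)
            deme_clone.append(True)
            deme_parent.append(offset + src)
        label = f"D{d + 1}"
        for i in range(n):
            individuals.append(f"{label}_{i + 1:03d}")
            populations.append(label)
        calls_idx.extend(deme_calls)
        is_clone.extend(deme_clone)
        parent.extend(deme_parent)
        offset += n

    idx = np.stack(calls_idx)                      # (N, L, 2) allele indices
    calls = allele_sizes[np.arange(L)[None, :, None], idx]  # fragment sizes

    # null alleles: at the chosen locus, a hidden null segregates at
    # frequency q; heterozygote carrier (visible, null) shows as visible
    # homozygote, null homozygote fails to amplify -> MISSING.
    if config.null_allele_freq > 0.0:
        l0 = config.null_allele_locus
        q = config.null_allele_freq
        N = calls.shape[0]
        null_copies = rng.random((N, 2)) < q
        both_null = null_copies.all(axis=1)
        one_null = null_copies.any(axis=1) & ~both_null
        which_null = null_copies[:, 1].astype(int)  # index of the null copy
        for i in np.flatnonzero(one_null):
            visible = calls[i, l0, 1 - which_null[i]]
            calls[i, l0] = visible
        calls[both_null, l0] = 0

    if config.missing_rate > 0.0:
        drop = rng.random(calls.shape[:2]) < config.missing_rate
        calls[drop] = 0

    matrix = GenotypeMatrix(
        individuals=individuals,
        populations=populations,
        loci=[
            LocusMeta(name=f"L{l + 1}", motif_length=config.motif_length)
            for l in range(L)
        ],
        calls=calls,
    )
    return SimulatedDataset(
        genotypes=matrix,
        is_clone=np.asarray(is_clone, dtype=bool),
        parent=np.asarray(parent, dtype=np.int64),
        deme_frequencies=freqs,
        allele_sizes=allele_sizes,
        config=config,
    )
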