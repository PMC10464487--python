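"""Reading and writing codominant genotype tables.

Two on-disk dialects are supported: the classic genepop text format
(2- or 3-digit allele codes, ``Pop`` blocks) and a flat CSV with two
columns per locus.  Alleles are integer fragment sizes in base pairs;
a whole-genotype zero code means the sample failed to score at that
locus (MISSING).  The in-memory container is :class:`GenotypeMatrix`.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LocusMeta",
    "GenotypeMatrix",
    "GenepopDialectError",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_csv_genotypes",
    "write_csv_genotypes",
    "missing_summary",
    "read_distance_matrix",
    "write_distance_matrix",
]


class GenepopParseError(ValueError):
    """Structural problem in a genepop file (ragged rows, no Pop block...)."""


class GenepopDialectError(ValueError):
    """Allele field width inconsistent with the declared digit count."""


@dataclass(frozen=True)
class LocusMeta:
    """Metadata for one microsatellite locus.

    Parameters
    ----------
    name
        Locus identifier, unique within a dataset.
    motif_length
        Base pairs per repeat unit (>= 1); used for stepwise-mutation
        distance arithmetic.
    size_range
        Optional (min bp, max bp) of expected fragment sizes.
    """

    name: str
    motif_length: int = 1
    size_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")


@dataclass
class GenotypeMatrix:
    """Individuals x loci table of unordered diploid allele-size pairs.

    ``calls`` is an int array of shape ``(n_individuals, n_loci, 2)``;
    a missing genotype is stored as ``(0, 0)`` and non-missing pairs are
    order-normalised ``(low, high)`` with both alleles > 0.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[LocusMeta]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(self.populations) != n:
            raise ValueError("one population label required per individual")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual identifiers")
        if any(not p for p in self.populations):
            raise ValueError("population labels must be non-empty")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        # promote half-coded calls (one zero allele) to full MISSING
        half = (self.calls == 0).sum(axis=2) == 1
        if half.any():
            warnings.warn(
                f"{int(half.sum())} half-coded call(s) promoted to MISSING",
                stacklevel=2,
            )
            self.calls[half] = 0
        if (self.calls < 0).any():
            raise ValueError("negative allele sizes")
        self.calls = np.sort(self.calls, axis=2)

    # -- basic queries -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci); True where the call is MISSING."""
        return (self.calls == 0).all(axis=2)

    def population_names(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations) == population)
        if idx.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def subset(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
        )


# ---------------------------------------------------------------------------
# genepop dialect
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _split_genepop_row(line: str) -> tuple[str, list[str]]:
    if "," in line:
        name, _, rest = line.partition(",")
        return name.strip(), rest.split()
    fields = line.split()
    return fields[0], fields[1:]


def read_genepop(path: str | Path, digits: int | None = None) -> GenotypeMatrix:
    """Read a genepop file with 2- or 3-digit allele codes.

    The first line is a free-text title, followed by locus names (one
    per line, or comma-separated on one line), then ``Pop`` blocks of
    sample rows ``name , code code ...``.  The all-zero code is MISSING.
    Population labels are taken from the last comma-terminated sample
    name of each block when it is non-numeric, otherwise ``pop1``,
    ``pop2``...  ``digits`` (2 or 3) is inferred from field widths when
    not given.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenepopParseError(f"{path}: too short to be a genepop file")
    body = lines[1:]
    locus_names: list[str] = []
    i = 0
    while i < len(body) and not _POP_RE.match(body[i]):
        chunk = body[i].strip()
        if chunk:
            locus_names.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(body):
        raise GenepopParseError(f"{path}: no 'Pop' line found")
    if not locus_names:
        raise GenepopParseError(f"{path}: no locus names before first 'Pop'")

    pops: list[list[tuple[str, list[str]]]] = []
    for lineno, raw in enumerate(body[i:], start=i + 2):
        if _POP_RE.match(raw):
            pops.append([])
            continue
        if not raw.strip():
            continue
        name, codes = _split_genepop_row(raw)
        if len(codes) != len(locus_names):
            raise GenepopParseError(
                f"{path}:{lineno}: expected {len(locus_names)} allele codes, "
                f"got {len(codes)}"
            )
        pops[-1].append((name, codes))

    widths = {len(c) for block in pops for _, row in block for c in row}
    if digits is None:
        if widths <= {4}:
            digits = 2
        elif widths <= {6}:
            digits = 3
        else:
            raise GenepopDialectError(
                f"{path}: inconsistent allele field widths {sorted(widths)}"
            )
    elif widths - {2 * digits}:
        raise GenepopDialectError(
            f"{path}: field widths {sorted(widths)} incompatible with "
            f"digits={digits}"
        )

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    for p, block in enumerate(pops, start=1):
        if not block:
            raise GenepopParseError(f"{path}: empty Pop block {p}")
        # prefer a shared sample-name prefix (e.g. KA_001.. -> KA); fall
        # back to the conventional last-sample name, then to the index
        import os.path

        prefix = (
            os.path.commonprefix([name for name, _ in block])
            .rstrip("0123456789")
            .rstrip("_-.")
        )
        label = prefix if len(prefix) >= 2 else block[-1][0]
        if not label or label.replace(".", "").replace("-", "").isdigit():
            label = f"pop{p}"
        for name, codes in block:
            individuals.append(name)
            populations.append(label)
            rows.append(
                [(int(c[:digits]), int(c[digits:])) for c in codes]
            )
    # genepop sample names need not be unique across pops; disambiguate
    if len(set(individuals)) != len(individuals):
        counts: dict[str, int] = {}
        uniq = []
        for name in individuals:
            k = counts.get(name, 0)
            uniq.append(name if k == 0 else f"{name}.{k}")
            counts[name] = k + 1
        individuals = uniq

    calls = np.array(rows, dtype=np.int64)
    loci = [LocusMeta(name=nm) for nm in locus_names]
    return GenotypeMatrix(individuals, populations, loci, calls)


def write_genepop(
    matrix: GenotypeMatrix, path: str | Path, digits: int = 3, title: str = "clonepop export"
) -> None:
    """Write ``matrix`` as a genepop file re-readable by :func:`read_genepop`."""
    limit = 10**digits - 1
    if matrix.calls.max(initial=0) > limit:
        raise GenepopDialectError(
            f"allele size {matrix.calls.max()} exceeds {digits}-digit width"
        )
    if matrix.n_individuals == 0:
        raise ValueError("refusing to write a matrix with no individuals")
    out = [title]
    out.extend(loc.name for loc in matrix.loci)
    pop_order = matrix.population_names()
    pops = np.asarray(matrix.populations)
    for label in pop_order:
        out.append("Pop")
        for i in np.flatnonzero(pops == label):
            codes = " ".join(
                f"{a:0{digits}d}{b:0{digits}d}" for a, b in matrix.calls[i]
            )
            out.append(f"{matrix.individuals[i]} , {codes}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_csv_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a CSV with columns individual, population, <locus>.1, <locus>.2, ...

    Blank or zero cells are MISSING.
    """
    df = pd.read_csv(path, dtype={0: str, 1: str})
    if df.shape[1] < 4 or (df.shape[1] - 2) % 2:
        raise ValueError(
            f"{path}: expected individual, population plus an even number of "
            f"allele columns, got {df.shape[1]} columns"
        )
    allele_cols = list(df.columns[2:])
    loci: list[LocusMeta] = []
    for c1, c2 in zip(allele_cols[::2], allele_cols[1::2]):
        b1, _, s1 = c1.rpartition(".")
        b2, _, s2 = c2.rpartition(".")
        if not (b1 and b1 == b2 and s1 == "1" and s2 == "2"):
            raise ValueError(
                f"{path}: allele columns must come in '<locus>.1'/'<locus>.2' "
                f"pairs; got {c1!r}, {c2!r}"
            )
        loci.append(LocusMeta(name=b1))
    vals = df[allele_cols].fillna(0).to_numpy(dtype=np.int64)
    calls = vals.reshape(len(df), len(loci), 2)
    return GenotypeMatrix(
        individuals=[str(x) for x in df.iloc[:, 0]],
        populations=[str(x) for x in df.iloc[:, 1]],
        loci=loci,
        calls=calls,
    )


def write_csv_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    cols: dict[str, object] = {
        "individual": matrix.individuals,
        "population": matrix.populations,
    }
    for j, loc in enumerate(matrix.loci):
        cols[f"{loc.name}.1"] = matrix.calls[:, j, 0]
        cols[f"{loc.name}.2"] = matrix.calls[:, j, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# summaries and distance matrices
# ---------------------------------------------------------------------------

def missing_summary(matrix: GenotypeMatrix) -> dict[str, pd.Series]:
    """Percent missing calls (%NA) per population and per locus.

    %NA = 100 * missing calls / total calls within the stratum.
    """
    miss = matrix.missing_mask
    per_locus = pd.Series(
        100.0 * miss.mean(axis=0),
        index=[loc.name for loc in matrix.loci],
        name="pct_missing",
    )
    pops = np.asarray(matrix.populations)
    per_pop = pd.Series(
        {p: 100.0 * miss[pops == p].mean() for p in matrix.population_names()},
        name="pct_missing",
    )
    for name, frac in per_locus.items():
        if frac == 100.0:
            logger.warning("locus %s has no scored calls (100%% missing)", name)
    return {"per_population": per_pop, "per_locus": per_locus}


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled square TSV distance matrix; validates symmetry."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    arr = df.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValueError(f"{path}: matrix is not symmetric")
    return df


def write_distance_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
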