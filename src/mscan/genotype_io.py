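"""Data model and I/O for multi-population microsatellite genotypes.

Genotypes are diploid, multiallelic, with alleles coded as positive integers
(repeat counts or fragment lengths; 0 is reserved for missing). The interchange
format is GENEPOP text (2- or 3-digit allele encodings); marker positions come
from a tab-separated map with columns ``locus  chromosome  start_bp  end_bp``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mscan")

__all__ = [
    "LocusInfo",
    "MarkerMap",
    "GenotypeDataset",
    "AlleleCountTable",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_marker_map",
    "write_marker_map",
    "allele_counts",
    "enumerate_syntenic_pairs",
]

MISSING = 0


class GenepopParseError(ValueError):
    """Raised when a GENEPOP file violates the dialect rules."""


@dataclass(frozen=True)
class LocusInfo:
    """One mapped marker: name, chromosome label and bp interval.

    ``chromosome`` is a free-form label ("1", "20", "NA"); unmapped loci use
    ``None`` positions. Intervals occasionally arrive with start > end; they
    are normalized to (min, max) with a warning, coordinates 1-based inclusive.
    """

    name: str
    chromosome: str = "NA"
    start_bp: int | None = None
    end_bp: int | None = None

    def __post_init__(self) -> None:
        s, e = self.start_bp, self.end_bp
        if s is not None and e is not None and s > e:
            logger.warning(
                "locus %s: start_bp %d > end_bp %d; normalizing to (min, max)",
                self.name, s, e,
            )
            object.__setattr__(self, "start_bp", e)
            object.__setattr__(self, "end_bp", s)
        s, e = self.start_bp, self.end_bp
        if s is not None and e is not None and e - s > 10_000_000:
            # microsatellite amplicons are < 1 kb; a multi-Mb interval is a
            # likely typo in the source map — keep it but flag it
            logger.warning(
                "locus %s: interval spans %.1f Mb; suspect coordinates",
                self.name, (e - s) / 1e6,
            )

    @property
    def midpoint(self) -> float | None:
        if self.start_bp is None or self.end_bp is None:
            return None
        return 0.5 * (self.start_bp + self.end_bp)


class MarkerMap:
    """Ordered collection of :class:`LocusInfo` with unique names."""

    def __init__(self, loci: Iterable[LocusInfo]):
        self.loci: list[LocusInfo] = list(loci)
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            dupes = {n for n in names if names.count(n) > 1}
            raise ValueError(f"duplicate locus names in marker map: {sorted(dupes)}")
        self._by_name = {l.name: l for l in self.loci}

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, name: str) -> LocusInfo:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.loci]


@dataclass
class GenotypeDataset:
    """Diploid genotypes for several populations at shared loci.

    ``genotypes[p]`` is an ``(n_individuals, n_loci, 2)`` integer array for
    population ``p``; allele code 0 marks a missing gene copy (both copies of
    a genotype are missing together in GENEPOP, but the container allows
    either). Allele order within a genotype carries no information.
    """

    populations: list[str]
    loci: list[str]
    genotypes: list[np.ndarray]
    individual_names: list[list[str]] | None = None

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("dataset must contain at least one population")
        if len(self.populations) != len(self.genotypes):
            raise ValueError("populations and genotype blocks differ in length")
        for p, g in zip(self.populations, self.genotypes):
            g = np.asarray(g, dtype=np.int64)
            if g.ndim != 3 or g.shape[1] != len(self.loci) or g.shape[2] != 2:
                raise ValueError(
                    f"population {p}: genotype array must be (n, {len(self.loci)}, 2)"
                )
            if (g < 0).any():
                raise ValueError(f"population {p}: negative allele codes")
        self.genotypes = [np.asarray(g, dtype=np.int64) for g in self.genotypes]

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_individuals(self) -> list[int]:
        return [g.shape[0] for g in self.genotypes]

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def pop_index(self, pop: str | int) -> int:
        if isinstance(pop, (int, np.integer)):
            return int(pop)
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeDataset":
        idx = [self.locus_index(l) for l in loci]
        return GenotypeDataset(
            populations=list(self.populations),
            loci=list(loci),
            genotypes=[g[:, idx, :].copy() for g in self.genotypes],
            individual_names=self.individual_names,
        )

    def subset_populations(self, pops: Sequence[str | int]) -> "GenotypeDataset":
        idx = [self.pop_index(p) for p in pops]
        return GenotypeDataset(
            populations=[self.populations[i] for i in idx],
            loci=list(self.loci),
            genotypes=[self.genotypes[i].copy() for i in idx],
            individual_names=(
                [self.individual_names[i] for i in idx]
                if self.individual_names is not None else None
            ),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        if self.populations != other.populations or self.loci != other.loci:
            return False
        for a, b in zip(self.genotypes, other.genotypes):
            if a.shape != b.shape:
                return False
            # unordered allele pairs: compare sorted
            if not np.array_equal(np.sort(a, axis=2), np.sort(b, axis=2)):
                return False
        return True


@dataclass
class AlleleCountTable:
    """Per-population allele -> gene-copy count map for one locus.

    The sufficient statistic for every frequency-based test in the scan.
    """

    locus: str
    populations: list[str]
    counts: list[dict[int, int]]

    @property
    def n_pop(self) -> list[int]:
        return [sum(c.values()) for c in self.counts]

    def pooled(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.counts:
            for a, k in c.items():
                out[a] = out.get(a, 0) + k
        return out

    def alleles(self) -> list[int]:
        return sorted(self.pooled().keys())

    def to_matrix(self) -> tuple[np.ndarray, list[int]]:
        """(n_pops, n_alleles) count matrix plus the allele column labels."""
        alleles = self.alleles()
        mat = np.zeros((len(self.counts), len(alleles)), dtype=np.int64)
        for i, c in enumerate(self.counts):
            for j, a in enumerate(alleles):
                mat[i, j] = c.get(a, 0)
        return mat, alleles


# ---------------------------------------------------------------------------
# GENEPOP reader / writer
# ---------------------------------------------------------------------------

def _parse_genotype_token(tok: str, lineno: int) -> tuple[int, int]:
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise GenepopParseError(
            f"line {lineno}: malformed genotype token {tok!r} "
            "(expected 4 or 6 digits)"
        )
    if not tok.isdigit():
        raise GenepopParseError(f"line {lineno}: malformed genotype token {tok!r}")
    return int(tok[:w]), int(tok[w:])


def read_genepop(path: str | Path) -> GenotypeDataset:
    """Read a GENEPOP file into a :class:`GenotypeDataset`.

    Accepts 2- and 3-digit allele encodings, ``POP``/``Pop``/``pop``
    delimiters, and locus names one per line or comma-separated. The
    individual label is everything before the last comma on a genotype row.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise GenepopParseError(f"{path}: empty file")
    # title line is lines[0]; locus names follow until first POP
    loci: list[str] = []
    i = 1
    pop_starts: list[int] = []
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i >= len(lines):
        raise GenepopParseError(f"{path}: no POP delimiter found")
    if not loci:
        raise GenepopParseError(f"{path}: no locus names before first POP")

    populations: list[str] = []
    blocks: list[list[list[tuple[int, int]]]] = []
    names: list[list[str]] = []
    while i < len(lines):
        assert lines[i].strip().lower() == "pop"
        populations.append(f"pop{len(populations) + 1}")
        blocks.append([])
        names.append([])
        i += 1
        while i < len(lines) and lines[i].strip().lower() != "pop":
            line = lines[i]
            if line.strip():
                if "," not in line:
                    raise GenepopParseError(
                        f"line {i + 1}: genotype row without comma separator"
                    )
                label, _, geno = line.rpartition(",")
                toks = geno.split()
                if len(toks) != len(loci):
                    raise GenepopParseError(
                        f"line {i + 1}: individual {label.strip()!r} has "
                        f"{len(toks)} genotypes, expected {len(loci)}"
                    )
                row = [_parse_genotype_token(t, i + 1) for t in toks]
                blocks[-1].append(row)
                names[-1].append(label.strip())
            i += 1

    genotypes = []
    for block in blocks:
        arr = np.array(block, dtype=np.int64).reshape(len(block), len(loci), 2)
        genotypes.append(arr)
    # first population name doubles as nothing: GENEPOP has no population names;
    # keep positional names (pop1..popN)
    return GenotypeDataset(
        populations=populations, loci=loci, genotypes=genotypes,
        individual_names=names,
    )


def write_genepop(
    ds: GenotypeDataset,
    path: str | Path,
    title: str = "mscan dataset",
    digits: int = 3,
) -> None:
    """Write a dataset as GENEPOP text (allele 0 = missing).

    ``digits`` is the per-allele width (2 or 3); codes must fit in it.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10 ** digits - 1
    maxcode = max((int(g.max()) for g in ds.genotypes if g.size), default=0)
    if maxcode > limit:
        raise ValueError(
            f"allele code {maxcode} not representable with {digits}-digit width"
        )
    out = [title]
    out.extend(ds.loci)
    for p, g in enumerate(ds.genotypes):
        out.append("POP")
        labels = (
            ds.individual_names[p]
            if ds.individual_names is not None
            else [f"{ds.populations[p]}_{k + 1}" for k in range(g.shape[0])]
        )
        for k in range(g.shape[0]):
            toks = [
                f"{g[k, l, 0]:0{digits}d}{g[k, l, 1]:0{digits}d}"
                for l in range(len(ds.loci))
            ]
            out.append(f"{labels[k]}, " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Marker map TSV
# ---------------------------------------------------------------------------

def read_marker_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"locus", "chromosome", "start_bp", "end_bp"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker map must have columns {sorted(required)}")

    def _pos(x: str) -> int | None:
        return None if x in ("", "NA") else int(x)

    return MarkerMap(
        LocusInfo(
            name=row["locus"],
            chromosome=row["chromosome"] or "NA",
            start_bp=_pos(row["start_bp"]),
            end_bp=_pos(row["end_bp"]),
        )
        for _, row in df.iterrows()
    )


def write_marker_map(mmap: MarkerMap, path: str | Path) -> None:
    rows = [
        {
            "locus": l.name,
            "chromosome": l.chromosome,
            "start_bp": "NA" if l.start_bp is None else l.start_bp,
            "end_bp": "NA" if l.end_bp is None else l.end_bp,
        }
        for l in mmap
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sufficient statistics
# ---------------------------------------------------------------------------

def allele_counts(ds: GenotypeDataset, locus: str) -> AlleleCountTable:
    """Tally gene copies per allele per population at one locus."""
    li = ds.locus_index(locus)
    counts: list[dict[int, int]] = []
    for g in ds.genotypes:
        calls = g[:, li, :].ravel()
        calls = calls[calls != MISSING]
        vals, cnts = np.unique(calls, return_counts=True)
        counts.append({int(v): int(c) for v, c in zip(vals, cnts)})
    return AlleleCountTable(locus=locus, populations=list(ds.populations),
                            counts=counts)


def enumerate_syntenic_pairs(
    mmap: MarkerMap,
) -> list[tuple[str, str, str, float]]:
    """All unordered locus pairs sharing a (non-missing) chromosome.

    Returns ``(locusA, locusB, chromosome, midpoint_distance_bp)`` sorted by
    chromosome then distance; pairs lacking positions get distance ``nan``
    and sort last within their chromosome.
    """
    by_chrom: dict[str, list[LocusInfo]] = {}
    for l in mmap:
        if l.chromosome != "NA":
            by_chrom.setdefault(l.chromosome, []).append(l)
    pairs = []
    for chrom, loci in sorted(by_chrom.items()):
        for a, b in itertools.combinations(loci, 2):
            if a.midpoint is not None and b.midpoint is not None:
                d = abs(a.midpoint - b.midpoint)
            else:
                d = float("nan")
            pairs.append((a.name, b.name, chrom, d))
    pairs.sort(key=lambda t: (t[2], float("inf") if np.isnan(t[3]) else t[3]))
    return pairs
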