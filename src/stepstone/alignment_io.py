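"""Alignment and population-map input, haplotype collapsing, distances.

Everything downstream — diversity statistics, AMOVA-style ``PhiST``,
Fu's Fs, the ABC model-selection bridge — consumes the containers
defined here: a :class:`SequenceAlignment`, a :class:`PopulationMap`
assigning samples to populations, the :class:`HaplotypeSpectrum` of
per-population haplotype counts, and the :class:`DifferenceMatrix` of
pairwise nucleotide differences.

Missing data rule (applied uniformly): ``N`` and ``-`` are treated as
missing.  Two sequences are the same haplotype when they agree at every
site where both are scored; pairwise differences and compared-site
counts use pairwise deletion of missing sites.  IUPAC ambiguity codes
other than ``N`` are mapped to ``N`` with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from stepstone.errors import (
    AlignmentLengthError,
    EmptyInputError,
    InsufficientSampleError,
    InvalidSymbolError,
    MappingError,
    UnknownPopulationError,
)

# Base encoding used internally: A,C,G,T -> 0..3, missing (N, -) -> -1.
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1, "-": -1}
_AMBIGUITY = set("RYSWKMBDHV")  # IUPAC codes collapsed to N
MISSING = -1


@dataclass
class SequenceAlignment:
    """A trimmed multiple alignment of mtDNA sequences.

    Attributes
    ----------
    ids : list of str
        Unique sequence identifiers, in input order.
    sequences : list of str
        Uppercase sequences over ``{A, C, G, T, N, -}``, all of length
        :attr:`length`.
    locus_name : str
        Free-text locus label (e.g. ``"CytB"``).
    """

    ids: list[str]
    sequences: list[str]
    locus_name: str = ""
    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence identifiers")
        if self.sequences:
            lengths = {len(s) for s in self.sequences}
            if len(lengths) > 1:
                raise AlignmentLengthError(
                    f"sequences have unequal lengths: {sorted(lengths)}"
                )
            if self.length == 0:
                raise AlignmentLengthError("zero-length alignment")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def encoded(self) -> np.ndarray:
        """Integer-coded matrix, shape ``(n, L)``; missing sites are -1."""
        if self._encoded is None:
            arr = np.empty((self.n, self.length), dtype=np.int8)
            for i, s in enumerate(self.sequences):
                arr[i] = [_BASE_CODE[c] for c in s]
            self._encoded = arr
        return self._encoded

    def subset(self, ids: Sequence[str]) -> "SequenceAlignment":
        """Alignment restricted to ``ids`` (kept in the order given)."""
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return SequenceAlignment(
            ids=list(ids),
            sequences=[self.sequences[r] for r in rows],
            locus_name=self.locus_name,
        )

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.sequences):
                fh.write(f">{sid}\n{seq}\n")


@dataclass
class PopulationMap:
    """Sample-to-population assignment with optional geography.

    ``assignment`` maps every sequence identifier to a population label.
    ``region`` and ``coordinates`` (decimal-degree ``(lat, lon)``) are
    keyed by population label and optional.
    """

    assignment: dict[str, str]
    region: dict[str, str] = field(default_factory=dict)
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for pop in self.assignment.values():
            seen.setdefault(pop)
        return list(seen)

    def members(self, population: str) -> list[str]:
        if population not in self.populations:
            raise UnknownPopulationError(population)
        return [i for i, p in self.assignment.items() if p == population]

    def sample_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for pop in self.assignment.values():
            sizes[pop] = sizes.get(pop, 0) + 1
        return sizes

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PopulationMap":
        """Read a two-column (id, population) TSV; lat/lon columns optional."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        cols = list(df.columns)
        assignment = dict(zip(df[cols[0]], df[cols[1]]))
        coords: dict[str, tuple[float, float]] = {}
        if "lat" in df.columns and "lon" in df.columns:
            for _, row in df.iterrows():
                coords[row[cols[1]]] = (float(row["lat"]), float(row["lon"]))
        return cls(assignment=assignment, coordinates=coords)

    def write_tsv(self, path: str | Path) -> None:
        rows = []
        for sid, pop in self.assignment.items():
            row = {"id": sid, "population": pop}
            if pop in self.coordinates:
                row["lat"], row["lon"] = self.coordinates[pop]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class HaplotypeSpectrum:
    """Per-population counts of distinct haplotypes.

    ``counts`` has one row per population (order of ``populations``) and
    one column per haplotype (order of ``haplotypes``); entries are
    non-negative integers summing to the total sample size ``n``.
    """

    haplotypes: list[str]
    populations: list[str]
    counts: np.ndarray
    assignments: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    def population_counts(self, population: str) -> np.ndarray:
        if population not in self.populations:
            raise UnknownPopulationError(population)
        return self.counts[self.populations.index(population)]

    def restrict(self, population: str) -> "HaplotypeSpectrum":
        """Single-population spectrum, dropping haplotypes absent there."""
        row = self.population_counts(population)
        keep = np.flatnonzero(row > 0)
        return HaplotypeSpectrum(
            haplotypes=[self.haplotypes[j] for j in keep],
            populations=[population],
            counts=row[keep].reshape(1, -1).copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=self.populations,
            columns=[f"H{j + 1}" for j in range(self.k)],
        )


@dataclass
class DifferenceMatrix:
    """Pairwise nucleotide-difference counts under pairwise deletion.

    ``d[i, j]`` counts sites where sequences ``i`` and ``j`` are both
    scored and disagree; ``sites_compared[i, j]`` counts the jointly
    scored sites.
    """

    d: np.ndarray
    sites_compared: np.ndarray
    ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def _clean_sequence(raw: str, identifier: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - set(_BASE_CODE) - _AMBIGUITY
    if bad:
        raise InvalidSymbolError(
            f"sequence {identifier!r} contains invalid symbols {sorted(bad)}"
        )
    amb = set(seq) & _AMBIGUITY
    if amb:
        warnings.warn(
            f"sequence {identifier!r}: ambiguity codes {sorted(amb)} mapped to N",
            stacklevel=3,
        )
        seq = "".join("N" if c in _AMBIGUITY else c for c in seq)
    return seq


def read_alignment(path: str | Path, locus_name: str = "") -> SequenceAlignment:
    """Read an aligned FASTA file.

    Sequences are uppercased, ``U`` is treated as ``T``, and IUPAC
    ambiguity codes other than ``N`` are converted to ``N`` with a
    warning.  Raises :class:`EmptyInputError` for an empty file and
    :class:`AlignmentLengthError` when sequence lengths differ.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [_clean_sequence(str(r.seq), r.id) for r in records]
    return SequenceAlignment(ids=ids, sequences=seqs, locus_name=locus_name)


def alignment_from_arrays(
    encoded: np.ndarray, ids: Iterable[str] | None = None, locus_name: str = ""
) -> SequenceAlignment:
    """Build an alignment from an integer-coded matrix (inverse of
    :meth:`SequenceAlignment.encoded`)."""
    lookup = np.array(list("ACGT"))
    seqs = []
    for row in encoded:
        chars = np.where(row >= 0, lookup[np.clip(row, 0, 3)], "N")
        seqs.append("".join(chars))
    if ids is None:
        ids = [f"s{i}" for i in range(len(seqs))]
    return SequenceAlignment(ids=list(ids), sequences=seqs, locus_name=locus_name)


def collapse_haplotypes(
    aln: SequenceAlignment, pm: PopulationMap
) -> HaplotypeSpectrum:
    """Collapse sequences into haplotypes, counted by population.

    Two sequences belong to the same haplotype when they agree at every
    site where both are scored (``N``/``-`` missing).  A sequence whose
    missing sites make it compatible with several established haplotypes
    is assigned to the first-encountered compatible one, which makes the
    collapse deterministic in input order.
    """
    if aln.n == 0:
        raise EmptyInputError("empty alignment")
    unmapped = [i for i in aln.ids if i not in pm.assignment]
    if unmapped:
        raise MappingError(f"ids missing from population map: {unmapped[:5]}")

    enc = aln.encoded()
    if not (enc == MISSING).any():
        # complete data: haplotype identity is exact row equality
        uniq, first_idx, inverse = np.unique(
            enc, axis=0, return_index=True, return_inverse=True
        )
        order = np.argsort(first_idx)  # first-encounter order, as the greedy path
        rank = np.empty(len(order), dtype=int)
        rank[order] = np.arange(len(order))
        assignment = rank[inverse].tolist()
        reps = [uniq[i] for i in order]
        return _spectrum_from_assignment(aln, pm, reps, assignment)
    reps: list[np.ndarray] = []  # consensus representative per haplotype
    assignment: list[int] = []
    for i in range(aln.n):
        seq = enc[i]
        placed = False
        for h, rep in enumerate(reps):
            both = (seq != MISSING) & (rep != MISSING)
            if not np.any(seq[both] != rep[both]):
                assignment.append(h)
                # fill sites the representative is missing but this copy has
                fill = (rep == MISSING) & (seq != MISSING)
                rep[fill] = seq[fill]
                placed = True
                break
        if not placed:
            reps.append(seq.copy())
            assignment.append(len(reps) - 1)
    return _spectrum_from_assignment(aln, pm, reps, assignment)


def _spectrum_from_assignment(
    aln: SequenceAlignment,
    pm: PopulationMap,
    reps: list[np.ndarray],
    assignment: list[int],
) -> HaplotypeSpectrum:
    populations = pm.populations
    pop_index = {p: r for r, p in enumerate(populations)}
    counts = np.zeros((len(populations), len(reps)), dtype=int)
    for i, sid in enumerate(aln.ids):
        counts[pop_index[pm.assignment[sid]], assignment[i]] += 1

    lookup = np.array(list("ACGT"))
    hap_strings = [
        "".join(np.where(r >= 0, lookup[np.clip(r, 0, 3)], "N")) for r in reps
    ]
    return HaplotypeSpectrum(
        haplotypes=hap_strings,
        populations=populations,
        counts=counts,
        assignments=list(assignment),
    )


def pairwise_differences(aln: SequenceAlignment) -> DifferenceMatrix:
    """Pairwise difference and compared-site counts for all sequence pairs.

    Differences are raw mismatch counts at jointly scored sites (no
    substitution-model correction), i.e. p-distance numerators.
    """
    if aln.n < 2:
        raise InsufficientSampleError(f"need at least 2 sequences, got {aln.n}")
    enc = aln.encoded()
    n, L = enc.shape
    present = enc != MISSING  # (n, L) bool
    if present.all():
        sites = np.full((n, n), L, dtype=np.int32)
    else:
        p = present.astype(np.float32)
        sites = (p @ p.T).astype(np.int32)
    # only sites with >= 2 distinct non-missing states can contribute to d
    hi = np.where(present, enc, np.int8(-100)).max(axis=0)
    lo = np.where(present, enc, np.int8(100)).min(axis=0)
    variable = hi > lo
    enc_v = enc[:, variable]
    pres_v = present[:, variable]
    d = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        diff = (enc_v[i] != enc_v) & pres_v[i] & pres_v
        d[i] = diff.sum(axis=1)
    np.fill_diagonal(d, 0)
    return DifferenceMatrix(d=d, sites_compared=sites, ids=list(aln.ids))


def private_haplotype_fraction(
    spectrum: HaplotypeSpectrum, focal: str
) -> tuple[int, float]:
    """Count and percentage of the focal population's private haplotypes.

    A haplotype is private when it occurs in the focal population and in
    no other population of the spectrum; the percentage is relative to
    the number of haplotypes observed in the focal population.
    """
    if focal not in spectrum.populations:
        raise UnknownPopulationError(focal)
    row = spectrum.population_counts(focal)
    if row.sum() == 0:
        raise UnknownPopulationError(f"population {focal!r} has no samples")
    others = spectrum.counts[
        [i for i, p in enumerate(spectrum.populations) if p != focal]
    ]
    other_totals = others.sum(axis=0) if len(others) else np.zeros_like(row)
    observed = row > 0
    private = observed & (other_totals == 0)
    count = int(private.sum())
    percent = 100.0 * count / int(observed.sum())
    return count, percent


def spectrum_report(spectrum: HaplotypeSpectrum) -> pd.DataFrame:
    """Per-population sample size, haplotype count, and private fraction."""
    rows = []
    for pop in spectrum.populations:
        counts = spectrum.population_counts(pop)
        n_pop = int(counts.sum())
        k_pop = int((counts > 0).sum())
        priv, pct = private_haplotype_fraction(spectrum, pop)
        rows.append(
            {
                "population": pop,
                "n": n_pop,
                "n_haplotypes": k_pop,
                "private": priv,
                "pct_private": pct,
            }
        )
    return pd.DataFrame(rows)
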