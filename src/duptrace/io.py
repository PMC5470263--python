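"""Readers, writers and validated domain containers for the pipeline's file formats.

External formats: FASTA for alignments, newick for trees, TSV for the
group map, the lineage-signature table and all reports. Alignment columns
are 0-based half-open everywhere inside the package; every file format and
report uses 1-based inclusive columns, and the conversion happens only at
this I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

#: Characters allowed in an alignment row. Ambiguity codes other than N are
#: rejected because the signature screen needs exact single-character matches.
ALPHABET = frozenset("ACGT-N")

#: Characters that do not carry comparable nucleotide information.
MISSING_CHARS = frozenset("-N")

FASTA_LINE_WIDTH = 70


class DataError(ValueError):
    """Base class for input-validation failures."""


class AlignmentError(DataError):
    """Ragged rows, bad characters or duplicate ids in an alignment."""


class CrossReferenceError(DataError):
    """Ids in one input that do not match another input."""


class FormatError(DataError):
    """A file that cannot be parsed in its declared format."""


def _normalize_row(raw: str) -> str:
    return raw.upper().replace("U", "T")


class Alignment:
    """A fixed-length nucleotide alignment over {A, C, G, T, -, N}.

    Rows are uppercased and RNA U is mapped to T on construction. Ids must
    be unique and all rows the same (nonzero) length.
    """

    def __init__(self, ids: Sequence[str], seqs: Sequence[str]):
        if len(ids) != len(seqs):
            raise AlignmentError("ids and seqs must have equal length")
        if not ids:
            raise FormatError("alignment contains no sequences")
        seqs = [_normalize_row(s) for s in seqs]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: row lengths {sorted(lengths)} differ"
            )
        (n_cols,) = lengths
        if n_cols < 1:
            raise AlignmentError("alignment must have at least one column")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if list(ids).count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        for sid, s in zip(ids, seqs):
            bad = set(s) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains unsupported characters {sorted(bad)}; "
                    "only A, C, G, T, -, N are accepted"
                )
        self.ids: tuple[str, ...] = tuple(ids)
        self.seqs: tuple[str, ...] = tuple(seqs)
        self.n_cols: int = n_cols
        self._index = {sid: k for k, sid in enumerate(self.ids)}
        self._array: np.ndarray | None = None

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def array(self) -> np.ndarray:
        """(n_seqs, n_cols) array of single characters (dtype ``<U1``)."""
        if self._array is None:
            self._array = np.array([list(s) for s in self.seqs], dtype="<U1")
        return self._array

    def row(self, seq_id: str) -> str:
        try:
            return self.seqs[self._index[seq_id]]
        except KeyError:
            raise CrossReferenceError(f"unknown sequence id {seq_id!r}") from None

    def index_of(self, seq_id: str) -> int:
        try:
            return self._index[seq_id]
        except KeyError:
            raise CrossReferenceError(f"unknown sequence id {seq_id!r}") from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.ids == other.ids
            and self.seqs == other.seqs
        )

    def __repr__(self) -> str:
        return f"Alignment(n_seqs={self.n_seqs}, n_cols={self.n_cols})"


@dataclass(frozen=True)
class GroupMap:
    """Species and higher-group (e.g. order) labels per sequence id."""

    species: Mapping[str, str]
    group: Mapping[str, str]

    def __post_init__(self):
        if set(self.species) != set(self.group):
            raise CrossReferenceError("species and group maps cover different ids")
        for sid in self.species:
            if not self.species[sid] or not self.group[sid]:
                raise DataError(f"empty species/group label for id {sid!r}")

    def ids_of_species(self, species: str) -> list[str]:
        return sorted(sid for sid, sp in self.species.items() if sp == species)

    def ids_of_group(self, group: str) -> list[str]:
        return sorted(sid for sid, g in self.group.items() if g == group)

    def species_names(self) -> list[str]:
        return sorted(set(self.species.values()))

    def group_names(self) -> list[str]:
        return sorted(set(self.group.values()))

    def label_for(self, seq_id: str, group_by: str) -> str:
        if group_by == "species":
            return self.species[seq_id]
        if group_by == "group":
            return self.group[seq_id]
        raise ValueError(f"group_by must be 'species' or 'group', got {group_by!r}")

    def __len__(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class SignatureSite:
    """One diagnostic column: 1-based position and the two lineage variants."""

    column: int  # 1-based alignment column
    variant_a: str
    variant_b: str

    def __post_init__(self):
        if self.column < 1:
            raise DataError(f"signature columns are 1-based; got {self.column}")
        for v, name in ((self.variant_a, "variantA"), (self.variant_b, "variantB")):
            if len(v) != 1 or v not in "ACGT":
                raise DataError(f"{name} must be a single base in ACGT, got {v!r}")
        if self.variant_a == self.variant_b:
            raise DataError(
                f"column {self.column}: variantA equals variantB ({self.variant_a!r})"
            )


class SignatureTable:
    """Ordered diagnostic columns with their lineage-A and lineage-B variants.

    Holds, for real data, tables such as the 16-site exon-3 signature that
    distinguishes the two MHCIIB paralog lineages; for simulations, the true
    diagnostic columns.
    """

    def __init__(self, sites: Sequence[SignatureSite], n_cols: int | None = None):
        sites = list(sites)
        if not sites:
            raise DataError("signature table is empty")
        cols = [s.column for s in sites]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise DataError(f"signature columns must be strictly increasing: {cols}")
        if n_cols is not None and cols[-1] > n_cols:
            raise DataError(
                f"signature column {cols[-1]} exceeds alignment length {n_cols}"
            )
        self.sites: tuple[SignatureSite, ...] = tuple(sites)

    @property
    def columns(self) -> list[int]:
        """1-based columns, ascending."""
        return [s.column for s in self.sites]

    @property
    def columns0(self) -> np.ndarray:
        """0-based column indices, ascending."""
        return np.array([s.column - 1 for s in self.sites], dtype=int)

    @property
    def variants_a(self) -> np.ndarray:
        return np.array([s.variant_a for s in self.sites], dtype="<U1")

    @property
    def variants_b(self) -> np.ndarray:
        return np.array([s.variant_b for s in self.sites], dtype="<U1")

    def __len__(self) -> int:
        return len(self.sites)

    def __eq__(self, other) -> bool:
        return isinstance(other, SignatureTable) and self.sites == other.sites


def report_header(seed: int | None = None) -> str:
    """Comment line placed at the top of every TSV report."""
    line = f"# duptrace {__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line


# ---------------------------------------------------------------------------
# FASTA

def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment, uppercase it, map U to T, and validate."""
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Bio raises assorted ValueErrors
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="") for sid, s in zip(aln.ids, aln.seqs)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_LINE_WIDTH)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Group map TSV  (columns: seq_id, species, group)

def read_groups(path: str | Path, aln: Alignment) -> GroupMap:
    """Read the seq_id→(species, group) table and cross-check it against ``aln``."""
    df = _read_tsv(path)
    required = {"seq_id", "species", "group"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing required columns {sorted(missing_cols)}")
    ids = df["seq_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate seq_id rows")
    tsv_ids, aln_ids = set(ids), set(aln.ids)
    if tsv_ids != aln_ids:
        missing = sorted(aln_ids - tsv_ids)
        extra = sorted(tsv_ids - aln_ids)
        parts = []
        if missing:
            parts.append(f"missing from table: {missing}")
        if extra:
            parts.append(f"not in alignment: {extra}")
        raise CrossReferenceError(f"{path}: id mismatch; " + "; ".join(parts))
    species = dict(zip(ids, df["species"].fillna("").astype(str)))
    group = dict(zip(ids, df["group"].fillna("").astype(str)))
    return GroupMap(species=species, group=group)


def write_groups(groups: GroupMap, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(report_header(seed) + "\n")
        fh.write("seq_id\tspecies\tgroup\n")
        for sid in sorted(groups.species):
            fh.write(f"{sid}\t{groups.species[sid]}\t{groups.group[sid]}\n")


# ---------------------------------------------------------------------------
# Signature table TSV  (columns: column, variantA, variantB; 1-based columns)

def read_signature(path: str | Path, aln: Alignment) -> SignatureTable:
    df = _read_tsv(path)
    required = {"column", "variantA", "variantB"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing required columns {sorted(missing_cols)}")
    sites = [
        SignatureSite(int(r.column), str(r.variantA), str(r.variantB))
        for r in df.itertuples()
    ]
    return SignatureTable(sites, n_cols=aln.n_cols)


def write_signature(
    sig: SignatureTable, path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(report_header(seed) + "\n")
        fh.write("column\tvariantA\tvariantB\n")
        for s in sig.sites:
            fh.write(f"{s.column}\t{s.variant_a}\t{s.variant_b}\n")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df


# ---------------------------------------------------------------------------
# Newick

def read_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a dendropy tree."""
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise FormatError(f"malformed newick: {exc}") from exc


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to newick with branch lengths at 10 significant digits."""
    out = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )
    return out.strip()


def read_newick_file(path: str | Path) -> dendropy.Tree:
    return read_newick(Path(path).read_text())


def write_newick_file(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")
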