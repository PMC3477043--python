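"""Dataset and alignment I/O.

This module owns the bundled binding-site dataset — 125 eukaryotic β-tubulin
paclitaxel-binding-site (PBS) residue strings with organism, family, accession
and sensitivity-group metadata, shipped as a plain TSV so the transcription is
auditable — plus readers for precomputed multiple sequence alignments (FASTA /
Clustal) and writers for projection tables.

The bundled strings cover the 14 variable positions of the 22-residue binding
site (author numbering of the reference structure). The 8 strictly conserved
positions carry no variance and are not part of the strings.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO

from .errors import AlignmentShapeError, AlphabetError, ContractError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AA20 + GAP

#: Families as used in the bundled dataset (the four eukaryotic kingdoms
#: sampled, plus the human isotype panel which originates in the animal table).
FAMILIES = ("animal", "fungi", "plant", "protist", "isotype")

#: Residue numbers (author numbering of the ligand-bound reference structure)
#: of the 14 variable binding-site positions, in string order. Positions 23,
#: 26, 229, 233, 272, 277 and 278 are pinned by the mutational record the
#: dataset annotates; the remainder are the best structural annotation of the
#: other variable contact-shell positions.
PBS_VARIABLE_POSITIONS = (22, 23, 26, 226, 229, 233, 236, 272, 276, 277, 278, 369, 370, 371)

#: The 8 strictly conserved binding-site positions (not in the strings).
PBS_CONSERVED_POSITIONS = (27, 217, 230, 237, 274, 275, 320, 360)


def column_of(position: int) -> int:
    """Return the string/alignment column index of a variable binding-site residue number."""
    try:
        return PBS_VARIABLE_POSITIONS.index(position)
    except ValueError:
        raise ContractError(
            f"residue {position} is not one of the 14 variable binding-site positions"
        ) from None


@dataclass(frozen=True)
class PBSRecord:
    """One organism's binding-site residue string with its metadata.

    ``family`` is the five-way label (``isotype`` for the human isotype
    panel); ``table`` records which source table the row came from, so family
    counts and the "fit without isotypes" variant are both expressible.
    """

    organism: str
    family: str
    table: str
    accession: str
    pbs_string: str
    group: str | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ContractError(f"unknown family {self.family!r}")
        bad = set(self.pbs_string) - set(ALPHABET)
        if bad:
            raise AlphabetError(
                f"{self.organism}: invalid symbol(s) {sorted(bad)} in PBS string"
            )
        if self.group is not None and self.group not in ("A", "B", "C", "D"):
            raise ContractError(f"invalid group label {self.group!r}")

    @property
    def is_isotype(self) -> bool:
        return self.family == "isotype"

    @property
    def isotype_name(self) -> str | None:
        """Short isotype name ('I', 'IIa', ... 'VI') for isotype records, else None."""
        if not self.is_isotype:
            return None
        return self.organism.split("isotype")[-1].strip(" ()")


@dataclass(frozen=True)
class AlignmentBlock:
    """An in-memory multiple sequence alignment over the 21-letter alphabet."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ContractError("one identifier per row required")
        if len(set(self.ids)) != len(self.ids):
            raise ContractError("alignment identifiers must be unique")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise AlignmentShapeError(f"rows have unequal lengths {sorted(widths)}")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - set(ALPHABET)
            if bad:
                raise AlphabetError(f"row {rid!r}: invalid symbol(s) {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise ContractError(f"no alignment row with id {rid!r}") from None


def load_bundled_dataset(include_isotypes: bool = True) -> list[PBSRecord]:
    """Load the bundled 125-sequence binding-site dataset.

    With ``include_isotypes=False`` the 8 human isotype rows are dropped,
    which is the default fitting set of the reproduction pipeline (the PCA is
    fitted on the 117 cross-species sequences and the isotypes are projected
    onto it afterwards).
    """
    text = resources.files("pocketpca.data").joinpath("pbs_dataset.tsv").read_text()
    records: list[PBSRecord] = []
    lines = text.strip("\n").split("\n")
    header = lines[0].split("\t")
    for line in lines[1:]:
        cells = dict(zip(header, line.split("\t")))
        rec = PBSRecord(
            organism=cells["organism"],
            family=cells["family"],
            table=cells["table"],
            accession=cells["accession"],
            pbs_string=cells["pbs_string"],
            group=cells.get("group") or None,
            flags=tuple(f for f in cells.get("flags", "").split(";") if f),
        )
        records.append(rec)
    if not include_isotypes:
        records = [r for r in records if not r.is_isotype]
    return records


def family_counts(records: Iterable[PBSRecord]) -> dict[str, int]:
    """Counts by source table (isotype rows counted under their animal-table origin)."""
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.table] = counts.get(rec.table, 0) + 1
    return counts


def variable_columns(rows: Sequence[str]) -> list[int]:
    """Indices of columns holding more than one distinct symbol."""
    if not rows:
        return []
    return [j for j in range(len(rows[0])) if len({r[j] for r in rows}) > 1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ContractError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def read_alignment(path: str | Path, format: str = "fasta") -> AlignmentBlock:
    """Read a FASTA or Clustal alignment; rows are uppercased and '.' gaps normalized."""
    if format not in ("fasta", "clustal"):
        raise ContractError(f"unsupported alignment format {format!r}")
    text = Path(path).read_text()
    try:
        msa = AlignIO.read(io.StringIO(text), format)
    except ValueError as exc:
        if "same length" in str(exc):
            raise AlignmentShapeError(str(exc)) from exc
        raise
    ids = tuple(rec.id for rec in msa)
    rows = tuple(str(rec.seq).upper().replace(".", GAP) for rec in msa)
    return AlignmentBlock(ids=ids, rows=rows)


def write_projection_table(
    records: Sequence[PBSRecord],
    coordinates,
    path: str | Path,
    groups: Sequence[str] | None = None,
) -> None:
    """Write a TSV of per-record PC1/PC2 coordinates (6-decimal fixed precision)."""
    import numpy as np

    coords = np.asarray(coordinates, dtype=float)
    if coords.shape != (len(records), 2):
        raise ContractError(
            f"need one (pc1, pc2) pair per record: got {coords.shape} for {len(records)} records"
        )
    if groups is not None and len(groups) != len(records):
        raise ContractError("one group label per record required")
    lines = ["organism\tfamily\taccession\tpbs_string\tpc1\tpc2\tgroup"]
    for i, rec in enumerate(records):
        group = groups[i] if groups is not None else (rec.group or "")
        lines.append(
            f"{rec.organism}\t{rec.family}\t{rec.accession}\t{rec.pbs_string}"
            f"\t{coords[i, 0]:.6f}\t{coords[i, 1]:.6f}\t{group}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_projection_table(path: str | Path):
    """Round-trip reader for :func:`write_projection_table` (returns a DataFrame)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", keep_default_na=False)
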