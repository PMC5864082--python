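"""Strain/barcode catalog and sample sheet handling.

Every strain in the barcoded deletion collection carries two unique
molecular barcodes, an UPTAG and a DOWNTAG, integrated with the deletion
cassette.  The catalog maps strains to their TAG sequences and ncRNA class;
the sample sheet maps 6-mer multiplexing indices to biological samples
(condition, growth stage, replicate).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from barfit.errors import SchemaError, ValidationError

NCRNA_CLASSES = ("tRNA", "snoRNA", "snRNA", "SUT", "CUT", "other")
CONDITIONS = ("Clim30", "Clim36", "Clim30LiCl", "Nlim30", "Nlim36", "Nlim30LiCl")
STAGES = ("P", "B", "ESS", "MSS", "LSS")

_DNA = frozenset("ACGT")
MIN_TAG_LEN = 15

CATALOG_COLUMNS = ["strain_id", "ncrna_name", "ncrna_class", "uptag", "downtag"]
SHEET_COLUMNS = ["sample_id", "index6", "condition", "stage", "replicate"]


def _check_dna(seq: str, what: str, row: int | None = None) -> None:
    if not seq or not _DNA.issuperset(seq):
        where = f" (row {row})" if row is not None else ""
        raise ValidationError(f"{what} {seq!r} is not a non-empty ACGT string{where}")


def infer_class(name: str) -> str:
    """Infer the ncRNA class from a display name.

    Compound deletions removing two overlapping transcripts (e.g.
    ``SUT233/CUT707``) take the class of the first-listed name; the full
    compound name is preserved elsewhere.
    """
    first = name.split("/")[0].strip()
    if first.upper().startswith("SUT"):
        return "SUT"
    if first.upper().startswith("CUT"):
        return "CUT"
    if first.upper().startswith("SNR"):
        return "snoRNA"
    if re.match(r"^t[A-Z]?\(", first):
        return "tRNA"
    return "other"


@dataclass(frozen=True)
class StrainRecord:
    """One barcoded deletion strain."""

    strain_id: str
    ncrna_name: str
    ncrna_class: str
    uptag: str
    downtag: str

    def __post_init__(self) -> None:
        _check_dna(self.uptag, f"uptag of {self.strain_id}")
        _check_dna(self.downtag, f"downtag of {self.strain_id}")
        if self.uptag == self.downtag:
            raise ValidationError(f"strain {self.strain_id}: uptag equals downtag")
        if self.ncrna_class not in NCRNA_CLASSES:
            raise ValidationError(
                f"strain {self.strain_id}: unknown ncrna_class {self.ncrna_class!r}"
            )
        if min(len(self.uptag), len(self.downtag)) < MIN_TAG_LEN:
            raise ValidationError(
                f"strain {self.strain_id}: TAGs shorter than {MIN_TAG_LEN} nt"
            )


@dataclass
class BarcodeCatalog:
    """Ordered collection of strains with an inverse TAG index.

    ``tag_index`` maps every TAG sequence to ``(strain_id, which)`` with
    ``which`` in ``{"up", "down"}``; TAG uniqueness is enforced over the
    union of all UPTAGs and DOWNTAGs.
    """

    records: list[StrainRecord] = field(default_factory=list)
    tag_index: dict[str, tuple[str, str]] = field(init=False)

    def __post_init__(self) -> None:
        index: dict[str, tuple[str, str]] = {}
        for rec in self.records:
            for which, tag in (("up", rec.uptag), ("down", rec.downtag)):
                if tag in index:
                    other = index[tag][0]
                    raise ValidationError(
                        f"TAG {tag} is shared by strains {other} and {rec.strain_id}"
                    )
                index[tag] = (rec.strain_id, which)
        self.tag_index = index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def strain_ids(self) -> list[str]:
        return [r.strain_id for r in self.records]

    def classes(self) -> dict[str, str]:
        """strain_id → ncRNA class."""
        return {r.strain_id: r.ncrna_class for r in self.records}

    def tag_lengths(self) -> list[int]:
        """Distinct TAG lengths present, ascending."""
        return sorted({len(t) for t in self.tag_index})


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    index6: str
    condition: str
    stage: str
    replicate: int


@dataclass
class SampleSheet:
    """Demultiplexing sheet for one sequencing run."""

    rows: list[SampleRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        seen_idx: set[str] = set()
        for i, row in enumerate(self.rows, start=1):
            if len(row.index6) != 6 or not _DNA.issuperset(row.index6):
                raise ValidationError(f"row {i}: index6 {row.index6!r} is not a 6-mer over ACGT")
            if row.condition not in CONDITIONS:
                raise ValidationError(f"row {i}: unknown condition {row.condition!r}")
            if row.stage not in STAGES:
                raise ValidationError(f"row {i}: unknown stage {row.stage!r}")
            if row.replicate < 1:
                raise ValidationError(f"row {i}: replicate must be a positive integer")
            if row.sample_id in seen_ids:
                raise ValidationError(f"row {i}: duplicate sample_id {row.sample_id!r}")
            if row.index6 in seen_idx:
                raise ValidationError(f"row {i}: duplicate index6 {row.index6!r}")
            seen_ids.add(row.sample_id)
            seen_idx.add(row.index6)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows]

    def index_map(self) -> dict[str, str]:
        """index6 → sample_id."""
        return {r.index6: r.sample_id for r in self.rows}

    def select(self, condition: str | None = None, stage: str | None = None) -> list[SampleRow]:
        out = []
        for r in self.rows:
            if condition is not None and r.condition != condition:
                continue
            if stage is not None and r.stage != stage:
                continue
            out.append(r)
        return out


def _read_tsv_rows(path: Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Read a TSV, skipping '#' comment lines; returns header + (lineno, fields)."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, "rt", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
            else:
                rows.append((lineno, fields))
    if header is None:
        raise SchemaError(f"{path}: empty file, no header row")
    return header, rows


def load_catalog(path: str | Path) -> BarcodeCatalog:
    """Load and validate a strain/barcode catalog TSV.

    Columns: strain_id, ncrna_name, ncrna_class, uptag, downtag.  The
    ncrna_class column may be omitted, in which case the class is inferred
    from the ncRNA name prefix (:func:`infer_class`).  Row order is
    preserved; '#' comment lines are ignored.
    """
    path = Path(path)
    header, rows = _read_tsv_rows(path)
    has_class = "ncrna_class" in header
    required = [c for c in CATALOG_COLUMNS if c != "ncrna_class" or has_class]
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing catalog column(s) {missing}")
    col = {name: header.index(name) for name in header}

    records = []
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise ValidationError(f"{path}:{lineno}: expected {len(header)} fields")
        name = fields[col["ncrna_name"]]
        cls = fields[col["ncrna_class"]] if has_class else infer_class(name)
        try:
            records.append(
                StrainRecord(
                    strain_id=fields[col["strain_id"]],
                    ncrna_name=name,
                    ncrna_class=cls,
                    uptag=fields[col["uptag"]],
                    downtag=fields[col["downtag"]],
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}:{lineno}: {err}") from None
    return BarcodeCatalog(records=records)


def write_catalog(catalog: BarcodeCatalog, path: str | Path) -> None:
    """Write a catalog TSV readable by :func:`load_catalog`."""
    with open(path, "wt", newline="\n") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for r in catalog.records:
            fh.write(f"{r.strain_id}\t{r.ncrna_name}\t{r.ncrna_class}\t{r.uptag}\t{r.downtag}\n")


def load_sample_sheet(path: str | Path) -> SampleSheet:
    """Load and validate a sample sheet TSV.

    Columns: sample_id, index6, condition, stage, replicate.
    """
    path = Path(path)
    header, rows = _read_tsv_rows(path)
    missing = [c for c in SHEET_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing sample-sheet column(s) {missing}")
    col = {name: header.index(name) for name in header}
    parsed = []
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise ValidationError(f"{path}:{lineno}: expected {len(header)} fields")
        try:
            rep = int(fields[col["replicate"]])
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: replicate is not an integer") from None
        parsed.append(
            SampleRow(
                sample_id=fields[col["sample_id"]],
                index6=fields[col["index6"]],
                condition=fields[col["condition"]],
                stage=fields[col["stage"]],
                replicate=rep,
            )
        )
    try:
        return SampleSheet(rows=parsed)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "wt", newline="\n") as fh:
        fh.write("\t".join(SHEET_COLUMNS) + "\n")
        for r in sheet.rows:
            fh.write(f"{r.sample_id}\t{r.index6}\t{r.condition}\t{r.stage}\t{r.replicate}\n")
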