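"""Barcode counting: multiplexed FASTQ → strain×sample count matrix.

A read identifies a strain when, after locating the constant flank that
precedes the TAG, the extracted candidate aligns to the full length of a
catalog TAG with at most one mismatch (Hamming).  Reads whose best match is
shared by two or more TAGs are ambiguous and discarded with a tally; counts
for a strain are the sum of its UPTAG and DOWNTAG hits.  Sample assignment
uses the exact 6-mer index carried in the read header.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from barfit.catalog import BarcodeCatalog, SampleSheet
from barfit.errors import FastqParseError
from barfit.sim import DOWNTAG_FLANK5, UPTAG_FLANK5, revcomp

UNASSIGNED = "unassigned"
NO_TAG = "no_tag"

_INDEX_RE = re.compile(r"index=([ACGTN]{6})")

ACCOUNTING_FIELDS = ("reads", "hits", "ambiguous", "unmatched", "no_tag")


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with its header-borne sample index."""

    read_id: str
    sequence: str
    quality: str
    index: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FastqParseError(
                f"read {self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class TagMatch:
    """Outcome of matching one extracted TAG against the catalog."""

    outcome: str  # hit | ambiguous | unmatched | no_tag
    strain_id: str | None = None
    which: str | None = None  # up | down
    mismatches: int | None = None


class TagMatcher:
    """Hash + per-length Hamming scan over a catalog's TAGs.

    Exact candidates resolve through the TAG hash; otherwise every catalog
    TAG of the same length is scanned by vectorized Hamming distance.  The
    contract is exact agreement with a brute-force scan of the catalog.
    """

    def __init__(self, catalog: BarcodeCatalog):
        self.catalog = catalog
        self.exact = catalog.tag_index
        self._by_len: dict[int, tuple[np.ndarray, list[tuple[str, str]]]] = {}
        buckets: dict[int, list[tuple[str, tuple[str, str]]]] = {}
        for tag, ident in catalog.tag_index.items():
            buckets.setdefault(len(tag), []).append((tag, ident))
        for L, items in buckets.items():
            arr = np.frombuffer("".join(t for t, _ in items).encode(), dtype=np.uint8)
            self._by_len[L] = (arr.reshape(len(items), L), [ident for _, ident in items])

    def tag_lengths(self) -> list[int]:
        return sorted(self._by_len)

    def match(self, tag: str) -> TagMatch:
        if not tag:
            return TagMatch(NO_TAG)
        ident = self.exact.get(tag)
        if ident is not None:
            return TagMatch("hit", strain_id=ident[0], which=ident[1], mismatches=0)
        entry = self._by_len.get(len(tag))
        if entry is None:
            return TagMatch("unmatched")
        arr, idents = entry
        q = np.frombuffer(tag.encode(), dtype=np.uint8)
        dists = (arr != q).sum(axis=1)
        at1 = np.nonzero(dists == 1)[0]
        if at1.size == 1:
            sid, which = idents[int(at1[0])]
            return TagMatch("hit", strain_id=sid, which=which, mismatches=1)
        if at1.size >= 2:
            return TagMatch("ambiguous")
        return TagMatch("unmatched")


def get_matcher(catalog: BarcodeCatalog) -> TagMatcher:
    matcher = getattr(catalog, "_matcher", None)
    if matcher is None or matcher.catalog is not catalog:
        matcher = TagMatcher(catalog)
        catalog._matcher = matcher
    return matcher


def match_tag(tag: str, catalog: BarcodeCatalog) -> TagMatch:
    """Match one extracted TAG against the catalog (≤1 mismatch rule)."""
    return get_matcher(catalog).match(tag)


def demultiplex(read: ReadRecord, sheet: SampleSheet) -> str:
    """Assign a read to a sample by exact 6-mer index match.

    Anything but an exact match — including indices containing N — returns
    :data:`UNASSIGNED`; single-mismatch rescue is deliberately not applied
    to avoid cross-sample bleed.
    """
    idx = read.index
    if idx is None:
        m = _INDEX_RE.search(read.read_id)
        idx = m.group(1) if m else None
    if idx is None:
        return UNASSIGNED
    return sheet.index_map().get(idx, UNASSIGNED)


def extract_tag(read: ReadRecord | str, flank5: str, expected_len: int) -> str | None:
    """Extract the TAG as the ``expected_len`` bases after the unique flank.

    Returns None (no TAG) when the flank is absent, occurs more than once,
    or fewer than ``expected_len`` bases follow it.
    """
    if not flank5:
        raise ValueError("flank5 must be non-empty")
    seq = read if isinstance(read, str) else read.sequence
    first = seq.find(flank5)
    if first < 0:
        return None
    if seq.find(flank5, first + 1) >= 0:
        return None
    start = first + len(flank5)
    if len(seq) - start < expected_len:
        return None
    return seq[start:start + expected_len]


@dataclass
class CountMatrix:
    """Integer strain×sample counts plus per-sample read accounting.

    The accounting identity ``hits + ambiguous + unmatched + no_tag =
    reads`` holds per sample; reads whose index matches no sample are
    tallied in ``unassigned``.
    """

    counts: pd.DataFrame
    accounting: pd.DataFrame
    unassigned: int = 0

    def __post_init__(self) -> None:
        assert (self.counts.to_numpy() >= 0).all()

    def check_accounting(self) -> bool:
        acc = self.accounting
        lhs = acc[["hits", "ambiguous", "unmatched", "no_tag"]].sum(axis=1)
        return bool((lhs == acc["reads"]).all())

    def write(self, counts_path: str | Path, accounting_path: str | Path | None = None,
              header_comment: str | None = None) -> None:
        for df, path in ((self.counts, counts_path), (self.accounting, accounting_path)):
            if path is None:
                continue
            with open(path, "wt", newline="\n") as fh:
                if header_comment:
                    fh.write(f"# {header_comment}\n")
                df.to_csv(fh, sep="\t", lineterminator="\n")

    @classmethod
    def read(cls, counts_path: str | Path, accounting_path: str | Path | None = None
             ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
        if accounting_path is not None:
            acc = pd.read_csv(accounting_path, sep="\t", index_col=0, comment="#")
        else:
            acc = pd.DataFrame(columns=list(ACCOUNTING_FIELDS))
        return cls(counts=counts.astype(int), accounting=acc)


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate FASTQ records; raises :class:`FastqParseError` on bad input."""
    path = Path(path)
    n = 0
    try:
        with _open_maybe_gz(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                m = _INDEX_RE.search(title)
                yield ReadRecord(read_id=title, sequence=seq.upper(), quality=qual,
                                 index=m.group(1) if m else None)
    except ValueError as err:
        raise FastqParseError(f"{path}: {err}", record_number=n + 1) from None


def _match_read(seq: str, matcher: TagMatcher, revcomp_scan: bool = False) -> TagMatch:
    """Apply flank-anchored extraction + catalog matching to one read."""
    lengths = matcher.tag_lengths()
    saw_flank = False
    hits: list[TagMatch] = []
    ambiguous = False
    for flank5 in (UPTAG_FLANK5, DOWNTAG_FLANK5):
        present = seq.find(flank5) >= 0
        if not present:
            continue
        saw_flank = True
        for L in lengths:
            cand = extract_tag(seq, flank5, L)
            if cand is None:
                continue
            m = matcher.match(cand)
            if m.outcome == "hit":
                hits.append(m)
            elif m.outcome == "ambiguous":
                ambiguous = True
    if not saw_flank:
        if revcomp_scan:
            return _match_read(revcomp(seq), matcher, revcomp_scan=False)
        return TagMatch(NO_TAG)
    exact = [h for h in hits if h.mismatches == 0]
    pool = exact if exact else hits
    if len(pool) == 1:
        return pool[0]
    if len(pool) >= 2 or ambiguous:
        return TagMatch("ambiguous")
    return TagMatch("unmatched")


def count_run(fastq_paths: Iterable[str | Path], catalog: BarcodeCatalog,
              sheet: SampleSheet, revcomp_scan: bool = False) -> CountMatrix:
    """Count TAG hits per strain per sample across FASTQ files.

    Per sample and strain the count is UPTAG hits + DOWNTAG hits.  Reads
    are demultiplexed by exact index; per-sample accounting of hits /
    ambiguous / unmatched / no-TAG reads is kept, and the accounting
    identity is guaranteed on return.
    """
    matcher = get_matcher(catalog)
    index_map = sheet.index_map()
    strain_pos = {sid: i for i, sid in enumerate(catalog.strain_ids)}
    sample_pos = {sid: j for j, sid in enumerate(sheet.sample_ids)}
    counts = np.zeros((len(strain_pos), len(sample_pos)), dtype=np.int64)
    acc = np.zeros((len(sample_pos), len(ACCOUNTING_FIELDS)), dtype=np.int64)
    unassigned = 0
    col = {f: k for k, f in enumerate(ACCOUNTING_FIELDS)}

    for path in fastq_paths:
        for read in iter_fastq(path):
            sample = index_map.get(read.index) if read.index else None
            if sample is None:
                unassigned += 1
                continue
            j = sample_pos[sample]
            acc[j, col["reads"]] += 1
            m = _match_read(read.sequence, matcher, revcomp_scan=revcomp_scan)
            if m.outcome == "hit":
                acc[j, col["hits"]] += 1
                counts[strain_pos[m.strain_id], j] += 1
            elif m.outcome == "ambiguous":
                acc[j, col["ambiguous"]] += 1
            elif m.outcome == "unmatched":
                acc[j, col["unmatched"]] += 1
            else:
                acc[j, col["no_tag"]] += 1

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(catalog.strain_ids, name="strain_id"),
                            columns=sheet.sample_ids),
        accounting=pd.DataFrame(acc, index=pd.Index(sheet.sample_ids, name="sample_id"),
                                columns=list(ACCOUNTING_FIELDS)),
        unassigned=unassigned,
    )
    assert cm.check_accounting()
    return cm
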