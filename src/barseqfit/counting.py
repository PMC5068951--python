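"""Barcode counting: indexed FASTQ reads -> per-mutant, per-sample count table.

Reads are laid out as ``sample index (3-4 nt) + constant spacer + strain
barcode``, padded to the sequencer read length.  Demultiplexing on the sample
index is exact (indices are too short to tolerate mismatches without
colliding samples); barcode matching tolerates up to one substitution with
strict rejection of ties, so a read is never arbitrarily assigned.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadLayout",
    "BarcodeCatalog",
    "CountResult",
    "load_sample_sheet",
    "validate_sample_sheet",
    "demultiplex_read",
    "match_barcode",
    "count_barcodes",
    "combine_tags",
]

#: Fixed spacer between the sample index and the strain barcode.  The real
#: primer scheme of archived Bar-seq runs is not modelled; the counter and the
#: simulator share this layout through manifests/config.
DEFAULT_SPACER = "GTCGA"

#: Single-end read length (cycles) the reads are padded to.
DEFAULT_READ_LENGTH = 42

TAG_CLASSES = ("up", "dn")
TAG_COMBINATIONS = ("sum", "uptag-only", "dntag-only", "keep-separate")

SAMPLE_SHEET_COLUMNS = ("sample_id", "index_seq", "tag_class", "condition", "batch")


@dataclass(frozen=True)
class ReadLayout:
    """Structure of a read: ``index + spacer + barcode`` padded to read_length.

    The index length varies per sample (3-4 nt) and is taken from the sample
    sheet; the spacer and barcode length are constant within a run.
    """

    spacer: str = DEFAULT_SPACER
    barcode_length: int = 20
    read_length: int = DEFAULT_READ_LENGTH

    def barcode_offset(self, index_seq: str) -> int:
        return len(index_seq) + len(self.spacer)

    def min_read_length(self, index_seq: str) -> int:
        return self.barcode_offset(index_seq) + self.barcode_length


class CatalogError(ValueError):
    pass


@dataclass
class BarcodeCatalog:
    """Mutant id -> (uptag, dntag) barcode table.

    ``table`` is indexed by mutant id with columns ``uptag_seq`` and
    ``dntag_seq``.  Barcode lengths must be uniform within a tag class and
    ids unique; sequences are stored upper-case.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = {"uptag_seq", "dntag_seq"} - set(t.columns)
        if missing:
            raise CatalogError(f"catalog missing columns: {sorted(missing)}")
        if len(t) == 0:
            raise CatalogError("empty barcode catalog")
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()][0]
            raise CatalogError(f"duplicate mutant id in catalog: {dup!r}")
        t = t.copy()
        for col in ("uptag_seq", "dntag_seq"):
            t[col] = t[col].astype(str).str.upper()
            if t[col].str.len().nunique() != 1:
                raise CatalogError(f"{col}: barcode lengths not uniform")
        self.table = t

    @property
    def mutants(self) -> list[str]:
        return list(self.table.index)

    def barcode_length(self, tag_class: str) -> int:
        col = _tag_column(tag_class)
        return len(self.table[col].iloc[0])

    def barcodes(self, tag_class: str) -> "pd.Series":
        """Barcode sequences for one tag class, indexed by mutant id."""
        return self.table[_tag_column(tag_class)]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeCatalog":
        table = pd.read_csv(path, sep="\t", dtype=str).set_index("mutant_id")
        return cls(table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="mutant_id")


def _tag_column(tag_class: str) -> str:
    if tag_class not in TAG_CLASSES:
        raise ValueError(f"tag_class must be one of {TAG_CLASSES}, got {tag_class!r}")
    return "uptag_seq" if tag_class == "up" else "dntag_seq"


# ---------------------------------------------------------------------------
# sample sheet


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample sheet.

    Required columns: sample_id, index_seq, tag_class (up|dn), condition,
    batch.  Optional ``fastq`` names the file each sample was sequenced in
    (default: one file per batch).  Within a file, sample indices must be
    unique and prefix-free so exact prefix demultiplexing is unambiguous.
    """
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    sheet = sheet.copy()
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    sheet["index_seq"] = sheet["index_seq"].astype(str).str.upper()
    sheet["batch"] = sheet["batch"].astype(str)
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup!r}")
    bad = ~sheet["tag_class"].isin(TAG_CLASSES)
    if bad.any():
        raise ValueError(f"tag_class must be in {TAG_CLASSES}: {sheet.loc[bad, 'tag_class'].tolist()}")
    if "fastq" not in sheet.columns:
        sheet["fastq"] = "batch" + sheet["batch"] + ".fastq"
    for fname, grp in sheet.groupby("fastq"):
        idx = grp["index_seq"].tolist()
        if len(set(idx)) != len(idx):
            raise ValueError(f"{fname}: two samples share an index")
        for a in idx:
            for b in idx:
                if a != b and b.startswith(a):
                    raise ValueError(f"{fname}: index {a!r} is a prefix of {b!r}; demultiplexing would be ambiguous")
    return sheet


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t", dtype=str))


def demultiplex_read(read_seq: str, index_to_sample: Mapping[str, str]) -> str | None:
    """Assign a read to a sample by exact, case-insensitive prefix match.

    ``index_to_sample`` maps (upper-case) index sequences to sample ids.
    Returns the sample id, or None for an unassigned read.  No mismatch
    tolerance: a 3-4 nt index cannot absorb errors without sample collisions.
    """
    seq = read_seq.upper()
    for length in {len(k) for k in index_to_sample}:
        sample = index_to_sample.get(seq[:length])
        if sample is not None:
            return sample
    return None


# ---------------------------------------------------------------------------
# barcode matching


class _BarcodeMatcher:
    """Hash-based exact + 1-mismatch matcher for one tag class.

    Exact lookups hit a dict; for one substitution, all 3L neighbors of the
    query are probed, which is O(L) per read and equivalent to a full
    Hamming scan because catalog barcodes are unique within a class.
    """

    def __init__(self, barcodes: pd.Series):
        self.length = len(barcodes.iloc[0])
        self.exact: dict[str, str] = {}
        for mutant, seq in barcodes.items():
            if seq in self.exact:
                raise CatalogError(f"barcode {seq!r} shared by {self.exact[seq]!r} and {mutant!r}")
            self.exact[seq] = str(mutant)

    def match(self, seq: str, max_mismatch: int) -> tuple[str | None, str]:
        """Return (mutant_id or None, status in assigned|unassigned|ambiguous)."""
        if len(seq) != self.length:
            return None, "unassigned"
        hit = self.exact.get(seq)
        if hit is not None:
            return hit, "assigned"
        if max_mismatch == 0:
            return None, "unassigned"
        hits: set[str] = set()
        chars = list(seq)
        for i, original in enumerate(chars):
            for base in "ACGT":
                if base == original:
                    continue
                chars[i] = base
                mutant = self.exact.get("".join(chars))
                if mutant is not None:
                    hits.add(mutant)
            chars[i] = original
        if len(hits) == 1:
            return hits.pop(), "assigned"
        if len(hits) > 1:
            return None, "ambiguous"
        return None, "unassigned"


def match_barcode(
    barcode_seq: str,
    catalog: BarcodeCatalog,
    tag_class: str,
    max_mismatch: int = 1,
) -> tuple[str | None, str]:
    """Match one barcode against the catalog.

    Returns ``(mutant_id, "assigned")`` for a unique hit within
    ``max_mismatch`` substitutions, ``(None, "ambiguous")`` when two or more
    catalog entries tie at the minimum distance, and ``(None, "unassigned")``
    otherwise (including length mismatches, which are counted in QC rather
    than raised).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    matcher = _BarcodeMatcher(catalog.barcodes(tag_class))
    return matcher.match(barcode_seq.upper(), max_mismatch)


# ---------------------------------------------------------------------------
# counting

QC_CATEGORIES = ("assigned", "unassigned_index", "unassigned_barcode", "ambiguous")


@dataclass
class CountResult:
    """Counts plus QC from one counting run.

    counts
        Mutants x samples integer matrix after tag combination.
    unit_counts
        Mutants x sequencing-unit matrix (one column per sample-sheet row),
        before tag combination.
    file_qc
        Per-FASTQ-file read accounting; the four categories sum to the
        total number of reads in the file.
    sample_qc
        Per-sample accounting of demultiplexed reads.
    """

    counts: pd.DataFrame
    unit_counts: pd.DataFrame
    file_qc: pd.DataFrame
    sample_qc: pd.DataFrame


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_barcodes(
    fastq_paths: Sequence[str | Path],
    catalog: BarcodeCatalog,
    sample_sheet: pd.DataFrame,
    layout: ReadLayout | None = None,
    max_mismatch: int = 1,
    tag_combination: str = "sum",
) -> CountResult:
    """Stream FASTQ files into a per-mutant count table with QC.

    Each read is demultiplexed by exact index prefix, then its barcode
    (extracted at the sample's layout offset) is matched against the catalog
    for the sample's tag class.  Row order follows the catalog, column order
    the sample sheet.  Memory is constant in the number of reads.
    """
    if layout is None:
        layout = ReadLayout(barcode_length=catalog.barcode_length("up"))
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    sheet = validate_sample_sheet(sample_sheet)
    paths = {Path(p).name: Path(p) for p in fastq_paths}
    needed = set(sheet["fastq"])
    missing_files = needed - set(paths)
    if missing_files:
        raise FileNotFoundError(f"sample sheet references FASTQ files not provided: {sorted(missing_files)}")

    matchers = {tc: _BarcodeMatcher(catalog.barcodes(tc)) for tc in TAG_CLASSES}
    for tc in TAG_CLASSES:
        if matchers[tc].length != layout.barcode_length:
            raise CatalogError(
                f"layout barcode_length {layout.barcode_length} != catalog "
                f"{tc}tag length {matchers[tc].length}"
            )

    mutant_index = {m: i for i, m in enumerate(catalog.mutants)}
    units = list(sheet["sample_id"])
    unit_index = {s: j for j, s in enumerate(units)}
    counts = np.zeros((len(mutant_index), len(units)), dtype=np.int64)

    file_qc_rows = {}
    sample_qc_arr = np.zeros((len(units), 4), dtype=np.int64)  # total, assigned, unassigned_barcode, ambiguous

    for fname, grp in sheet.groupby("fastq", sort=False):
        # per-sample lookups resolved once per file, not per read
        sample_info = {
            row.sample_id: (
                unit_index[row.sample_id],
                layout.barcode_offset(row.index_seq),
                matchers[row.tag_class],
            )
            for row in grp.itertuples(index=False)
        }
        index_to_sample = dict(zip(grp["index_seq"], grp["sample_id"]))
        index_lengths = sorted({len(i) for i in index_to_sample})
        bc_len = layout.barcode_length
        qc = dict.fromkeys(QC_CATEGORIES, 0)
        total = 0
        with _open_maybe_gzip(paths[fname]) as handle:
            try:
                for _title, seq, _qual in FastqGeneralIterator(handle):
                    total += 1
                    seq = seq.upper()
                    sample = None
                    for length in index_lengths:
                        sample = index_to_sample.get(seq[:length])
                        if sample is not None:
                            break
                    if sample is None:
                        qc["unassigned_index"] += 1
                        continue
                    unit, offset, matcher = sample_info[sample]
                    sample_qc_arr[unit, 0] += 1
                    mutant, status = matcher.match(seq[offset : offset + bc_len], max_mismatch)
                    if status == "assigned":
                        qc["assigned"] += 1
                        sample_qc_arr[unit, 1] += 1
                        counts[mutant_index[mutant], unit] += 1
                    elif status == "ambiguous":
                        qc["ambiguous"] += 1
                        sample_qc_arr[unit, 3] += 1
                    else:
                        qc["unassigned_barcode"] += 1
                        sample_qc_arr[unit, 2] += 1
            except ValueError as exc:  # truncated / malformed record
                raise ValueError(f"{fname}: malformed FASTQ near record {total + 1}: {exc}") from exc
        file_qc_rows[fname] = {"total_reads": total, **qc}
    sample_qc = pd.DataFrame(
        sample_qc_arr,
        index=units,
        columns=["total", "assigned", "unassigned_barcode", "ambiguous"],
    )

    unit_counts = pd.DataFrame(
        counts, index=pd.Index(catalog.mutants, name="mutant_id"), columns=units
    )
    combined = combine_tags(unit_counts, sheet, tag_combination)
    file_qc = pd.DataFrame.from_dict(file_qc_rows, orient="index").rename_axis("fastq")
    return CountResult(combined, unit_counts, file_qc, sample_qc)


def combine_tags(
    unit_counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    mode: str = "sum",
) -> pd.DataFrame:
    """Combine uptag/dntag sequencing units of the same biological sample.

    Units sharing (condition, batch) are treated as the two tag reads of one
    sample.  Modes: ``sum`` (default; adds the two tag counts, maximizing
    depth), ``uptag-only``, ``dntag-only``, ``keep-separate``.  Combined
    columns are labelled ``condition.batch``.
    """
    if mode not in TAG_COMBINATIONS:
        raise ValueError(f"tag_combination must be one of {TAG_COMBINATIONS}, got {mode!r}")
    sheet = sample_sheet.set_index("sample_id")
    if mode == "keep-separate":
        return unit_counts.copy()
    if mode in ("uptag-only", "dntag-only"):
        want = "up" if mode == "uptag-only" else "dn"
        keep = [s for s in unit_counts.columns if sheet.loc[s, "tag_class"] == want]
        sub = unit_counts[keep]
        labels = [f"{sheet.loc[s, 'condition']}.{sheet.loc[s, 'batch']}" for s in keep]
        sub = sub.set_axis(labels, axis=1)
        return sub
    # sum
    labels = [
        f"{sheet.loc[s, 'condition']}.{sheet.loc[s, 'batch']}" for s in unit_counts.columns
    ]
    out = unit_counts.T.groupby(pd.Index(labels, name="sample")).sum().T
    # preserve first-appearance column order
    seen: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    return out[seen]
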