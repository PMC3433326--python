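"""Domain types and readers/writers for the pipeline's inputs and outputs.

The central objects are a binary sample x fragment presence/absence matrix
(dominant markers such as AFLP), a per-sample metadata table, an aligned
plastid haplotype alignment with optional excluded regions, and flow-cytometry
fluorescence-ratio records.  File formats are plain delimited text (tab
canonical on write; tab/comma/semicolon auto-detected on read), aligned FASTA
for haplotypes, and a SplitsTree-dialect NEXUS Splits block for split systems.

Coordinates in files and reports are 1-based inclusive (the convention of the
alignment editors this mirrors); internally they are converted to 0-based
half-open.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ParseError, ValidationError

UNKNOWN = "unknown"

_ALIGNMENT_ALPHABET = set("ACGTN-")


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, matching how printed tables round."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# MarkerMatrix
# ---------------------------------------------------------------------------


@dataclass
class MarkerMatrix:
    """Binary presence/absence of sized fragments across samples.

    ``values[i, j]`` is 1 if sample ``sample_ids[i]`` carries fragment
    ``locus_labels[j]``.  Strictly binary: missing data are not supported;
    replicate mismatches model scoring noise instead.
    """

    sample_ids: list[str]
    locus_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_labels = [str(l) for l in self.locus_labels]
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(self.sample_ids) < 1 or len(self.locus_labels) < 1:
            raise ValidationError("marker matrix needs at least 1 sample and 1 locus")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id {dup!r}")
        if len(set(self.locus_labels)) != len(self.locus_labels):
            dup = _first_duplicate(self.locus_labels)
            raise ValidationError(f"duplicate locus label {dup!r}")
        if self.values.shape != (len(self.sample_ids), len(self.locus_labels)):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_labels)} loci"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"non-binary value {self.values[i, j]!r} at "
                f"({self.sample_ids[i]}, {self.locus_labels[j]})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_labels)

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.values[self.sample_ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def subset(self, sample_ids: Sequence[str]) -> "MarkerMatrix":
        try:
            idx = [self.sample_ids.index(s) for s in sample_ids]
        except ValueError:
            missing = [s for s in sample_ids if s not in self.sample_ids]
            raise KeyError(f"unknown sample ids {missing}") from None
        return MarkerMatrix(list(sample_ids), list(self.locus_labels), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.locus_labels)


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return ""


def _sniff_delimiter(line: str) -> str:
    counts = {d: line.count(d) for d in ("\t", ",", ";")}
    best = max(counts, key=lambda d: counts[d])
    if counts[best] == 0:
        raise ParseError("could not detect a tab/comma/semicolon delimiter")
    return best


def read_marker_matrix(path: str | os.PathLike | io.TextIOBase) -> MarkerMatrix:
    """Read a delimited 0/1 matrix: first row locus labels, first column sample ids."""
    text = _read_text(path)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty marker matrix file")
    delim = _sniff_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(delim)]
    loci = header[1:]
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(delim)]
        sid = cells[0]
        if len(cells) - 1 != len(loci):
            raise ParseError(f"row {sid!r} has {len(cells) - 1} cells, expected {len(loci)}")
        row = []
        for lab, cell in zip(loci, cells[1:]):
            if cell not in ("0", "1"):
                raise ParseError(f"non-binary cell {cell!r} at ({sid}, {lab})")
            row.append(int(cell))
        sample_ids.append(sid)
        rows.append(row)
    return MarkerMatrix(sample_ids, loci, np.array(rows, dtype=np.int8))


def write_marker_matrix(m: MarkerMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(m.locus_labels) + "\n")
        for sid, row in zip(m.sample_ids, m.values):
            fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def _read_text(path: str | os.PathLike | io.TextIOBase) -> str:
    if hasattr(path, "read"):
        return path.read()
    with open(path) as fh:
        return fh.read()


# ---------------------------------------------------------------------------
# SampleMeta
# ---------------------------------------------------------------------------


@dataclass
class SampleRecord:
    """Per-sample annotations; optional fields default to explicit 'unknown'."""

    sample_id: str
    taxon: str
    population: str
    locality: str = UNKNOWN
    cytotype: int | None = None  # ploidy multiplier (x); None = unknown
    haplotype: str | None = None  # single-letter code; None = unknown
    replicate_of: str | None = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded and not self.exclusion_reason:
            raise ValidationError(
                f"excluded sample {self.sample_id!r} must carry a nonempty reason"
            )


@dataclass
class SampleTable:
    """Collection of SampleRecord with the documented referential invariants."""

    records: list[SampleRecord]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate sample id {_first_duplicate(ids)!r} in metadata")
        known = set(ids)
        for r in self.records:
            if r.replicate_of is not None and r.replicate_of not in known:
                raise ValidationError(
                    f"replicate_of {r.replicate_of!r} of sample {r.sample_id!r} "
                    "does not point to an existing sample"
                )
        self._by_id = {r.sample_id: r for r in self.records}

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def non_excluded(self) -> list[SampleRecord]:
        return [r for r in self.records if not r.excluded]

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """(original, repeat) pairs for repeatability assessment."""
        return [(r.replicate_of, r.sample_id) for r in self.records if r.replicate_of]

    def summary(self) -> dict:
        recs = self.records
        return {
            "n_accessions": len(recs),
            "n_populations": len({r.population for r in recs}),
            "n_taxa": len({r.taxon for r in recs}),
            "n_excluded": sum(r.excluded for r in recs),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "taxon": [r.taxon for r in self.records],
                "population": [r.population for r in self.records],
                "locality": [r.locality for r in self.records],
                "cytotype": [r.cytotype for r in self.records],
                "haplotype": [r.haplotype for r in self.records],
                "replicate_of": [r.replicate_of for r in self.records],
                "excluded": [r.excluded for r in self.records],
                "exclusion_reason": [r.exclusion_reason for r in self.records],
            }
        )


_META_MANDATORY = ("sample_id", "taxon", "population")


def read_metadata(path: str | os.PathLike | io.TextIOBase) -> SampleTable:
    """Read the sample metadata table; sample_id, taxon and population are mandatory."""
    text = _read_text(path)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty metadata file")
    delim = _sniff_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(delim)]
    for col in _META_MANDATORY:
        if col not in header:
            raise ValidationError(f"metadata is missing mandatory column {col!r}")
    records = []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(delim)]
        d = dict(zip(header, cells))
        cyt = d.get("cytotype", "")
        hap = d.get("haplotype", "")
        records.append(
            SampleRecord(
                sample_id=d["sample_id"],
                taxon=d["taxon"],
                population=d["population"],
                locality=d.get("locality") or UNKNOWN,
                cytotype=int(cyt) if cyt and cyt != UNKNOWN else None,
                haplotype=hap if hap and hap != UNKNOWN else None,
                replicate_of=d.get("replicate_of") or None,
                excluded=d.get("excluded", "").lower() in ("1", "true", "yes"),
                exclusion_reason=d.get("exclusion_reason", ""),
            )
        )
    return SampleTable(records)


def write_metadata(meta: SampleTable, path: str | os.PathLike) -> None:
    cols = (
        "sample_id\ttaxon\tpopulation\tlocality\tcytotype\thaplotype\t"
        "replicate_of\texcluded\texclusion_reason\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for r in meta:
            fh.write(
                "\t".join(
                    [
                        r.sample_id,
                        r.taxon,
                        r.population,
                        r.locality,
                        UNKNOWN if r.cytotype is None else str(int(r.cytotype)),
                        UNKNOWN if r.haplotype is None else r.haplotype,
                        r.replicate_of or "",
                        "true" if r.excluded else "false",
                        r.exclusion_reason,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# HaploAlignment
# ---------------------------------------------------------------------------


@dataclass
class HaploAlignment:
    """Aligned plastid sequences plus 1-based inclusive excluded column intervals.

    Exclusions (e.g. poly-A stretches with ambiguous alignment) are stored, not
    applied; applying them and coding indels is the job of haplonet.code_alignment.
    """

    sequence_ids: list[str]
    sequences: list[str]
    excluded_regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence_ids:
            raise ValidationError("alignment contains no sequences")
        if len(self.sequence_ids) != len(self.sequences):
            raise ValidationError("sequence_ids and sequences differ in length")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            ragged = [
                sid
                for sid, s in zip(self.sequence_ids, self.sequences)
                if len(s) != len(self.sequences[0])
            ]
            raise ValidationError(f"ragged alignment; offending ids: {ragged}")
        for sid, s in zip(self.sequence_ids, self.sequences):
            bad = set(s) - _ALIGNMENT_ALPHABET
            if bad:
                raise ValidationError(f"sequence {sid!r} contains invalid symbols {sorted(bad)}")
        L = self.length
        regions = sorted(self.excluded_regions)
        for start, end in regions:
            if not (1 <= start <= end <= L):
                raise ValidationError(f"excluded region ({start}, {end}) outside 1..{L}")
        for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
            if s2 <= e1:
                raise ValidationError(f"excluded regions ({s1},{e1}) and ({s2},{e2}) overlap")
        self.excluded_regions = regions

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def excluded_columns(self) -> np.ndarray:
        """Boolean mask (0-based) over columns covered by an excluded region."""
        mask = np.zeros(self.length, dtype=bool)
        for start, end in self.excluded_regions:
            mask[start - 1 : end] = True
        return mask


def read_alignment(
    path: str | os.PathLike | io.TextIOBase,
    exclusions: Iterable[tuple[int, int]] = (),
) -> HaploAlignment:
    """Read an aligned FASTA; `exclusions` are 1-based inclusive column intervals."""
    handle = path if hasattr(path, "read") else open(path)
    try:
        recs = list(SeqIO.parse(handle, "fasta"))
    finally:
        if handle is not path:
            handle.close()
    if not recs:
        raise ParseError("empty or non-FASTA alignment file")
    return HaploAlignment(
        sequence_ids=[r.id for r in recs],
        sequences=[str(r.seq) for r in recs],
        excluded_regions=[(int(a), int(b)) for a, b in exclusions],
    )


def write_alignment(aln: HaploAlignment, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.sequence_ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


def read_region_exclusions(path: str | os.PathLike | io.TextIOBase) -> list[tuple[int, int]]:
    """Read a two-column (start, end) 1-based inclusive interval list."""
    text = _read_text(path)
    out = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#") or ln.lower().startswith("start"):
            continue
        parts = re.split(r"[\t,; ]+", ln)
        out.append((int(parts[0]), int(parts[1])))
    return out


# ---------------------------------------------------------------------------
# FcmRecord
# ---------------------------------------------------------------------------


@dataclass
class FcmRecord:
    """One flow-cytometry measurement: sample/standard G0/G1 fluorescence ratio."""

    sample_id: str
    ratio: float
    cv_percent: float
    species: str

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValidationError(f"FCM ratio of {self.sample_id!r} must be > 0")
        if self.cv_percent < 0:
            raise ValidationError(f"FCM CV of {self.sample_id!r} must be >= 0")


def read_fcm(path: str | os.PathLike | io.TextIOBase) -> list[FcmRecord]:
    text = _read_text(path)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty FCM file")
    delim = _sniff_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(delim)]
    for col in ("sample_id", "ratio", "cv_percent", "species"):
        if col not in header:
            raise ValidationError(f"FCM table is missing mandatory column {col!r}")
    out = []
    for ln in lines[1:]:
        d = dict(zip(header, (c.strip() for c in ln.split(delim))))
        out.append(
            FcmRecord(
                sample_id=d["sample_id"],
                ratio=float(d["ratio"]),
                cv_percent=float(d["cv_percent"]),
                species=d["species"],
            )
        )
    return out


def write_fcm(records: Sequence[FcmRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tratio\tcv_percent\tspecies\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.ratio:.6f}\t{r.cv_percent:.2f}\t{r.species}\n")


# ---------------------------------------------------------------------------
# NEXUS Splits block (SplitsTree dialect)
# ---------------------------------------------------------------------------


def write_splits_nexus(splits, path: str | os.PathLike) -> None:
    """Write a SplitSystem as a SplitsTree-readable NEXUS Taxa + Splits file.

    Split sides are written as 1-based taxon indices; the CYCLE line records
    the circular ordering.  Weights are kept to 10 decimals.
    """
    if not splits.splits:
        raise ValidationError("refusing to write an empty split system")
    taxa = splits.taxa
    n = len(taxa)
    with open(path, "w") as fh:
        fh.write("#nexus\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={n};\nTAXLABELS\n")
        for i, t in enumerate(taxa, 1):
            fh.write(f"[{i}] '{t}'\n")
        fh.write(";\nEND; [Taxa]\n\nBEGIN Splits;\n")
        fh.write(f"DIMENSIONS ntax={n} nsplits={len(splits.splits)};\n")
        fh.write("FORMAT labels=no weights=yes confidences=no intervals=no;\n")
        fh.write("CYCLE " + " ".join(str(i + 1) for i in splits.cycle) + ";\n")
        fh.write("MATRIX\n")
        for k, (side, w) in enumerate(splits.splits, 1):
            members = " ".join(str(i + 1) for i in sorted(side))
            fh.write(f"[{k}, size={len(side)}] \t {w:.10f} \t {members},\n")
        fh.write(";\nEND; [Splits]\n")


def read_splits_nexus(path: str | os.PathLike):
    """Read back a Splits-block NEXUS written by write_splits_nexus."""
    from .splits import SplitSystem  # local import to avoid a cycle

    with open(path) as fh:
        text = fh.read()
    tax_match = re.search(r"TAXLABELS\s*(.*?);", text, re.S)
    if not tax_match:
        raise ParseError("no TAXLABELS block found")
    taxa = re.findall(r"'([^']*)'", tax_match.group(1))
    cyc_match = re.search(r"CYCLE\s+([\d\s]+);", text)
    if not cyc_match:
        raise ParseError("no CYCLE line found")
    cycle = [int(x) - 1 for x in cyc_match.group(1).split()]
    mat_match = re.search(r"MATRIX\s*(.*?);", text, re.S)
    if not mat_match:
        raise ParseError("no Splits MATRIX found")
    entries = []
    for ln in mat_match.group(1).splitlines():
        ln = re.sub(r"\[[^\]]*\]", "", ln).strip().rstrip(",").strip()
        if not ln:
            continue
        parts = ln.split()
        weight = float(parts[0])
        side = frozenset(int(x) - 1 for x in parts[1:])
        entries.append((side, weight))
    return SplitSystem(taxa=taxa, cycle=cycle, splits=entries)
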