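"""Reference, annotation, sample-sheet and raw-tag input/output.

Conventions used throughout the package:

* internal alphabet is DNA (``ACGT``); ``U``/``u`` on input is normalized
  to ``T`` so that hairpin references (usually distributed as RNA) and
  sequencing reads (DNA) compare directly;
* all hairpin coordinates are 1-based and inclusive at both ends, so a
  mature spanning positions 60..80 is 21 nt long;
* identical read sequences within a sample are collapsed into a single
  :class:`Tag` carrying a multiplicity.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

log = logging.getLogger(__name__)

_DNA = set("ACGT")
_U_TO_T = str.maketrans("Uu", "Tt")


class ReferenceError(ValueError):
    """Malformed or inconsistent reference input."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA ``U`` to DNA ``T``."""
    return seq.translate(_U_TO_T).upper()


@dataclass(frozen=True)
class Hairpin:
    """A pre-miRNA hairpin reference sequence.

    ``id`` follows miRBase style (e.g. ``hsa-mir-143``); the species code is
    the 3-letter prefix. The sequence is validated to the DNA alphabet after
    U->T normalization.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _DNA
        if bad:
            raise ReferenceError(
                f"hairpin {self.id!r}: non-ACGTU characters {sorted(bad)}"
            )
        if not self.sequence:
            raise ReferenceError(f"hairpin {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def species(self) -> str:
        return self.id.split("-", 1)[0]

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice of the hairpin sequence."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(
                f"span {start}..{end} outside hairpin {self.id!r} (len {self.length})"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class MatureAnnotation:
    """A canonical mature miRNA located on one arm of a hairpin.

    ``start``/``end`` are 1-based inclusive hairpin coordinates; ``sequence``
    must equal the hairpin subsequence at that span.
    """

    hairpin_id: str
    mature_name: str
    arm: str  # "5p" or "3p"
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ReferenceError(f"{self.mature_name}: arm must be 5p or 3p")
        if not (1 <= self.start <= self.end):
            raise ReferenceError(
                f"{self.mature_name}: invalid span {self.start}..{self.end}"
            )
        if self.end - self.start + 1 != len(self.sequence):
            raise ReferenceError(
                f"{self.mature_name}: span length != sequence length"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def arm_name(self) -> str:
        """The arm-qualified name used by the nomenclature, e.g. hsa-miR-143-3p."""
        base = self.mature_name
        if base.endswith(("-5p", "-3p")):
            base = base[:-3]
        return f"{base}-{self.arm}"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    tissue: str
    donor_id: str
    prep_kit: str
    raw_library_size: int = 0

    def __post_init__(self) -> None:
        if not self.tissue or not self.prep_kit:
            raise ReferenceError(
                f"sample {self.sample_id!r}: tissue and prep_kit must be non-empty"
            )


@dataclass(frozen=True)
class Tag:
    """A collapsed read: one distinct sequence with its read multiplicity."""

    sequence: str
    multiplicity: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if not self.sequence:
            raise ValueError("empty tag sequence")


# ---------------------------------------------------------------------------
# readers / writers

def read_hairpin_fasta(path: str | Path) -> dict[str, Hairpin]:
    """Load hairpin references from FASTA, keyed by id.

    U is normalized to T; duplicate ids and non-ACGTU characters are
    rejected with an error naming the record.
    """
    hairpins: dict[str, Hairpin] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in hairpins:
            raise ReferenceError(f"duplicate hairpin id {rec.id!r} in {path}")
        hairpins[rec.id] = Hairpin(rec.id, normalize_sequence(str(rec.seq)))
    return hairpins


def write_hairpin_fasta(hairpins: Mapping[str, Hairpin], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hp in hairpins.values():
            fh.write(f">{hp.id}\n{hp.sequence}\n")


def read_mature_fasta(path: str | Path) -> dict[str, str]:
    """Load mature miRNA sequences (e.g. a decoy set) as name -> DNA string."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ReferenceError(f"duplicate mature id {rec.id!r} in {path}")
        out[rec.id] = normalize_sequence(str(rec.seq))
    return out


def _infer_arm(start: int, end: int, hairpin: Hairpin) -> str:
    # Midpoint of the mature span vs midpoint of the hairpin; exact center
    # counts as 5p (logged).
    span_mid = (start + end) / 2
    hp_mid = (1 + hairpin.length) / 2
    if span_mid == hp_mid:
        log.info(
            "mature at %d..%d sits exactly at the center of %s; calling 5p",
            start, end, hairpin.id,
        )
        return "5p"
    return "5p" if span_mid < hp_mid else "3p"


def locate_mature(mature_name: str, mature_seq: str, hairpin: Hairpin) -> MatureAnnotation:
    """Place a mature sequence on its hairpin by exact substring search.

    The 5'-most occurrence wins (multiple occurrences are logged); the arm is
    called from the position of the span midpoint relative to the hairpin
    midpoint.
    """
    seq = normalize_sequence(mature_seq)
    idx = hairpin.sequence.find(seq)
    if idx < 0:
        raise ReferenceError(
            f"mature {mature_name!r} does not occur in hairpin {hairpin.id!r}"
        )
    if hairpin.sequence.find(seq, idx + 1) >= 0:
        log.warning(
            "mature %s occurs more than once in hairpin %s; using the 5'-most span",
            mature_name, hairpin.id,
        )
    start, end = idx + 1, idx + len(seq)
    return MatureAnnotation(
        hairpin_id=hairpin.id,
        mature_name=mature_name,
        arm=_infer_arm(start, end, hairpin),
        start=start,
        end=end,
        sequence=seq,
    )


def _annotation_from_span(
    hairpin: Hairpin, mature_name: str, start: int, end: int
) -> MatureAnnotation:
    if not (1 <= start <= end <= hairpin.length):
        raise ReferenceError(
            f"annotation {mature_name!r}: span {start}..{end} outside "
            f"hairpin {hairpin.id!r} (length {hairpin.length})"
        )
    return MatureAnnotation(
        hairpin_id=hairpin.id,
        mature_name=mature_name,
        arm=_infer_arm(start, end, hairpin),
        start=start,
        end=end,
        sequence=hairpin.subseq(start, end),
    )


def read_annotations(
    path: str | Path, hairpins: Mapping[str, Hairpin]
) -> list[MatureAnnotation]:
    """Load mature annotations from a TSV or a miRBase-dialect GFF3.

    The TSV needs a header with columns ``hairpin_id``, ``mature_name``,
    ``start``, ``end`` (hairpin-relative, 1-based inclusive). The GFF3
    dialect uses the hairpin id as seqid, ``miRNA`` feature rows, and a
    ``Name=`` attribute. At most one 5p and one 3p annotation per hairpin.
    """
    path = Path(path)
    rows: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("##gff") or (
            "\t" in first and len(first.split("\t")) == 9 and not first.startswith("hairpin_id")
        ):
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ReferenceError(f"{path}: malformed GFF3 line: {line!r}")
                seqid, _, ftype, start, end, _, _, _, attrs = parts
                if ftype != "miRNA":
                    continue
                attr = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                name = attr.get("Name") or attr.get("ID")
                if name is None:
                    raise ReferenceError(f"{path}: miRNA row without Name/ID: {line!r}")
                rows.append((seqid, name, int(start), int(end)))
        else:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"hairpin_id", "mature_name", "start", "end"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ReferenceError(
                    f"{path}: TSV header must contain {sorted(required)}"
                )
            for row in reader:
                rows.append(
                    (row["hairpin_id"], row["mature_name"],
                     int(row["start"]), int(row["end"]))
                )

    annotations: list[MatureAnnotation] = []
    seen_arms: dict[tuple[str, str], str] = {}
    for hairpin_id, name, start, end in rows:
        if hairpin_id not in hairpins:
            raise ReferenceError(f"annotation {name!r}: unknown hairpin {hairpin_id!r}")
        ann = _annotation_from_span(hairpins[hairpin_id], name, start, end)
        key = (hairpin_id, ann.arm)
        if key in seen_arms:
            raise ReferenceError(
                f"hairpin {hairpin_id!r} has two {ann.arm} annotations "
                f"({seen_arms[key]!r}, {name!r})"
            )
        seen_arms[key] = name
        annotations.append(ann)
    return annotations


def write_annotations(annotations: Iterable[MatureAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("hairpin_id\tmature_name\tstart\tend\n")
        for a in annotations:
            fh.write(f"{a.hairpin_id}\t{a.mature_name}\t{a.start}\t{a.end}\n")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Load the sample sheet TSV (sample_id, tissue, donor_id, prep_kit)."""
    samples: list[SampleMeta] = []
    seen: set[str] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "tissue", "donor_id", "prep_kit"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ReferenceError(f"{path}: sample sheet must contain {sorted(required)}")
        for row in reader:
            sid = row["sample_id"]
            if sid in seen:
                raise ReferenceError(f"duplicate sample_id {sid!r}")
            seen.add(sid)
            samples.append(
                SampleMeta(sid, row["tissue"], row["donor_id"], row["prep_kit"])
            )
    return samples


def write_sample_sheet(samples: Iterable[SampleMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttissue\tdonor_id\tprep_kit\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.tissue}\t{s.donor_id}\t{s.prep_kit}\n")


def _multiplicity_from_header(header: str) -> int:
    # pre-collapsed dialect: ">name_xN" carries N identical reads
    if "_x" in header:
        tail = header.rsplit("_x", 1)[1]
        if tail.isdigit():
            return int(tail)
    return 1


def read_tags(
    path: str | Path, sample_id: str, fmt: str | None = None
) -> list[Tag]:
    """Read reads from FASTA/FASTQ and collapse identical sequences.

    ``fmt`` is inferred from the suffix when omitted. Headers of the form
    ``name_xN`` contribute N to the multiplicity. The result is sorted by
    sequence so it is independent of input order.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    counts: dict[str, int] = {}
    n_records = 0
    for rec in SeqIO.parse(str(path), fmt):
        n_records += 1
        seq = normalize_sequence(str(rec.seq))
        counts[seq] = counts.get(seq, 0) + _multiplicity_from_header(rec.id)
    if n_records == 0:
        log.warning("no reads found in %s", path)
    return [
        Tag(seq, mult, sample_id) for seq, mult in sorted(counts.items())
    ]
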