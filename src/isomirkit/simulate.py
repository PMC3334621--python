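"""Synthetic hairpin references and multi-sample read cohorts with truth.

The generator emulates a small-RNA sequencing experiment at desk scale:
random pre-miRNA hairpins carrying one 5p and one 3p mature each, tag
populations drawn from a mixture over the seven isomiR categories,
independent per-base substitution sequencing error, read-through into the
3' adaptor, cross-species decoy reads that cannot map to the target
hairpins, and a cohort of samples structured as tissue x donor x
library-prep kit. Designed effects — arm-switch hairpins, ac-pre-miRNA-like
hairpins (uniform mature 5' start, silent opposite arm, a trail of
templated 3' extensions) and orphan isomiR arms — are planted with full
ground truth, so every downstream analysis can be checked against its
design.

Hairpin sequences are uniform random; no secondary-structure realism is
attempted because none of the alignment or classification logic consumes
structure.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from isomirkit.alignment import AlignerParams, hamming_scan
from isomirkit.annotation import IsomiRFeatures, classify, render_name
from isomirkit.reference_io import (
    Hairpin,
    MatureAnnotation,
    SampleMeta,
    write_annotations,
    write_hairpin_fasta,
    write_sample_sheet,
)

_BASES = "ACGT"

DEFAULT_MIXTURE = {
    "canonical": 0.50,
    "start_only": 0.08,
    "end_only": 0.20,
    "substitution_only": 0.05,
    "shifted": 0.07,
    "nta3": 0.05,
    "mixed": 0.05,
}


@dataclass(frozen=True)
class SampleDesign:
    tissue: str
    donor_id: str
    prep_kit: str
    depth: int


DEFAULT_COHORT = (
    SampleDesign("heart", "d1", "SREK", 4000),
    SampleDesign("heart", "d1", "WTAK", 4000),
    SampleDesign("kidney", "d2", "SREK", 4000),
    SampleDesign("kidney", "d2", "WTAK", 4000),
    SampleDesign("liver", "d3", "SREK", 4000),
    SampleDesign("liver", "d3", "WTAK", 4000),
)


@dataclass(frozen=True)
class SimSpec:
    """Generator settings; the defaults define the standard study conditions.

    Hairpins are built as 5' flank + 5p mature + loop + 3p mature + 3'
    flank, giving lengths in the typical pre-miRNA range. Reads per sample
    follow ``category_mixture``; ``error_rate`` is the per-base
    substitution error; ``adaptor_read_through`` is the probability a read
    runs into the 3' adaptor (miRNA inserts are shorter than the read
    length, so read-through is the norm). The first ``n_switch`` hairpins
    are arm switchers (dominance flips in ``switch_tissues``), the next
    ``n_acpre`` are ac-pre-miRNA-like (5p-dominant), and the next
    ``n_orphan`` carry an orphan 3p arm that only ever emits a start-shift
    isomiR.
    """

    seed: int = 0
    n_hairpins: int = 20
    flank5_range: tuple[int, int] = (4, 8)
    loop_range: tuple[int, int] = (12, 16)
    flank3_range: tuple[int, int] = (4, 10)
    mature_len_range: tuple[int, int] = (20, 23)
    category_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    error_rate: float = 0.005
    adaptor_seq: str = "CTGCTGTACGGCCAAGGCG"
    adaptor_read_through: float = 1.0
    decoy_fraction: float = 0.001
    n_decoys: int = 5
    cohort: tuple[SampleDesign, ...] = DEFAULT_COHORT
    arm_bias: float = 0.7
    n_switch: int = 2
    switch_tissues: tuple[str, ...] = ("heart",)
    switch_bias: float = 0.85
    n_acpre: int = 1
    acpre_ext_fraction: float = 0.25
    acpre_ext_range: tuple[int, int] = (2, 8)
    n_orphan: int = 1
    min_tag_len: int = 20
    max_sub: int = 2

    def __post_init__(self) -> None:
        if self.n_hairpins < 1:
            raise ValueError("n_hairpins must be >= 1")
        total = sum(self.category_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category mixture sums to {total}, not 1")
        for p in (self.error_rate, self.adaptor_read_through, self.decoy_fraction,
                  self.arm_bias, self.switch_bias, self.acpre_ext_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if any(d.depth < 1 for d in self.cohort):
            raise ValueError("sample depths must be >= 1")
        if self.n_switch + self.n_acpre + self.n_orphan > self.n_hairpins:
            raise ValueError("designed hairpins exceed n_hairpins")

    # -- designed hairpin designations (by generation order) --------------
    def switch_ids(self) -> list[str]:
        return [f"syn-mir-{i + 1}" for i in range(self.n_switch)]

    def acpre_ids(self) -> list[str]:
        base = self.n_switch
        return [f"syn-mir-{base + i + 1}" for i in range(self.n_acpre)]

    def orphan_arms(self) -> list[tuple[str, str]]:
        base = self.n_switch + self.n_acpre
        return [(f"syn-mir-{base + i + 1}", "3p") for i in range(self.n_orphan)]

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["cohort"] = [asdict(s) for s in self.cohort]
        data["category_mixture"] = dict(self.category_mixture)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["cohort"] = tuple(SampleDesign(**s) for s in data["cohort"])
        for key in ("flank5_range", "loop_range", "flank3_range",
                    "mature_len_range", "acpre_ext_range"):
            data[key] = tuple(data[key])
        data["switch_tissues"] = tuple(data["switch_tissues"])
        return cls(**data)


@dataclass
class References:
    hairpins: dict[str, Hairpin]
    annotations: list[MatureAnnotation]
    decoys: dict[str, str]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _decoy_is_disjoint(
    decoy: str, hairpins: Mapping[str, Hairpin], min_len: int, max_sub: int
) -> bool:
    # no prefix of the decoy (down to the recursive minimum length) may
    # place on any hairpin within the substitution budget
    for length in range(len(decoy), min_len - 1, -1):
        prefix = decoy[:length]
        for hp in hairpins.values():
            if hamming_scan(prefix, hp, max_sub):
                return False
    return True


def make_references(spec: SimSpec) -> References:
    """Random hairpins with 5p/3p matures plus verified-disjoint decoys."""
    rng = np.random.default_rng(spec.seed)
    hairpins: dict[str, Hairpin] = {}
    annotations: list[MatureAnnotation] = []
    for i in range(spec.n_hairpins):
        hid = f"syn-mir-{i + 1}"
        flank5 = int(rng.integers(*spec.flank5_range, endpoint=True))
        loop = int(rng.integers(*spec.loop_range, endpoint=True))
        flank3 = int(rng.integers(*spec.flank3_range, endpoint=True))
        m5 = int(rng.integers(*spec.mature_len_range, endpoint=True))
        m3 = int(rng.integers(*spec.mature_len_range, endpoint=True))
        length = flank5 + m5 + loop + m3 + flank3
        seq = _rand_seq(rng, length)
        hp = Hairpin(hid, seq)
        hairpins[hid] = hp
        s5, e5 = flank5 + 1, flank5 + m5
        s3, e3 = e5 + loop + 1, e5 + loop + m3
        annotations.append(
            MatureAnnotation(hid, f"syn-miR-{i + 1}", "5p", s5, e5, hp.subseq(s5, e5))
        )
        annotations.append(
            MatureAnnotation(hid, f"syn-miR-{i + 1}", "3p", s3, e3, hp.subseq(s3, e3))
        )
    decoys: dict[str, str] = {}
    attempts = 0
    while len(decoys) < spec.n_decoys:
        attempts += 1
        if attempts > 200 * spec.n_decoys:
            raise RuntimeError("could not generate disjoint decoys")
        n = int(rng.integers(*spec.mature_len_range, endpoint=True))
        cand = _rand_seq(rng, n)
        if _decoy_is_disjoint(cand, hairpins, spec.min_tag_len, spec.max_sub):
            decoys[f"decoy-miR-{len(decoys) + 1}"] = cand
    return References(hairpins, annotations, decoys)


# ---------------------------------------------------------------------------
# variant construction

def _offset_ok(ann: MatureAnnotation, hp: Hairpin, ds: int, de: int, min_len: int) -> bool:
    start, end = ann.start + ds, ann.end + de
    return 1 <= start <= end <= hp.length and end - start + 1 >= min_len


def _draw_offset(rng: np.random.Generator) -> int:
    return int(rng.choice([-2, -1, 1, 2]))


def _draw_variant(
    rng: np.random.Generator,
    hp: Hairpin,
    ann: MatureAnnotation,
    category: str,
    spec: SimSpec,
) -> tuple[int, int, tuple[tuple[int, str, str], ...], str]:
    """(start, end, substitutions, nta_seq) realizing a category on an arm."""
    for _ in range(100):
        ds = de = 0
        subs: tuple[tuple[int, str, str], ...] = ()
        nta = ""
        if category == "start_only":
            ds = _draw_offset(rng)
        elif category == "end_only":
            de = _draw_offset(rng)
        elif category == "shifted":
            ds = de = _draw_offset(rng)
        elif category == "mixed":
            ds, de = _draw_offset(rng), _draw_offset(rng)
            if ds == de:
                continue
        elif category == "substitution_only":
            # avoid the 3'-terminal base: a lone terminal mismatch is
            # indistinguishable from a 1-nt non-templated addition and the
            # caller resolves that tie in favor of the NTA reading
            pos_in_tag = int(rng.integers(1, ann.length))  # 1..len-1
            hp_pos = ann.start + pos_in_tag - 1
            ref = hp.sequence[hp_pos - 1]
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            subs = ((hp_pos, ref, alt),)
        elif category == "nta3":
            k = int(rng.integers(1, 4))
            bases = []
            for j in range(k):
                pos = ann.end + 1 + j
                templ = hp.sequence[pos - 1] if pos <= hp.length else None
                choices = [b for b in _BASES if b != templ]
                bases.append(str(rng.choice(choices)))
            nta = "".join(bases)
        elif category != "canonical":
            raise ValueError(f"unknown category {category!r}")
        if not _offset_ok(ann, hp, ds, de, spec.min_tag_len):
            continue
        return ann.start + ds, ann.end + de, subs, nta
    raise RuntimeError(f"cannot realize category {category!r} on {ann.mature_name}")


def _templated_seq(
    hp: Hairpin, start: int, end: int, subs: Sequence[tuple[int, str, str]]
) -> str:
    chars = list(hp.subseq(start, end))
    for pos, _ref, alt in subs:
        chars[pos - start] = alt
    return "".join(chars)


class _UniqueCheck:
    """Verifies (with caching) that a templated sequence has a unique best
    placement at its intended position across all hairpins."""

    def __init__(self, hairpins: Mapping[str, Hairpin], max_sub: int) -> None:
        self.hairpins = hairpins
        self.max_sub = max_sub
        self.cache: dict[str, bool] = {}

    def unique(self, seq: str, hid: str, start: int, n_sub: int) -> bool:
        key = f"{seq}@{hid}:{start}"
        if key not in self.cache:
            ok = True
            for hp in self.hairpins.values():
                for p in hamming_scan(seq, hp, self.max_sub):
                    if (p.hairpin_id, p.start) == (hid, start):
                        continue
                    if p.n_sub <= n_sub:
                        ok = False
                        break
                if not ok:
                    break
            self.cache[key] = ok
        return self.cache[key]


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        chars[i] = str(rng.choice([b for b in _BASES if b != chars[i]]))
    return "".join(chars)


def simulate_reads(
    spec: SimSpec, refs: References
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Draw reads for every cohort sample; return reads and the truth table.

    Reads are ``(read_id, sequence)`` pairs per sample; truth rows record
    the intended placement, substitutions, NTA, category and name of every
    non-decoy read *before* error injection.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ann_by = {(a.hairpin_id, a.arm): a for a in refs.annotations}
    hairpin_ids = sorted(refs.hairpins)
    switch = set(spec.switch_ids())
    acpre = set(spec.acpre_ids())
    orphan = set(spec.orphan_arms())
    checker = _UniqueCheck(refs.hairpins, spec.max_sub)
    categories = sorted(spec.category_mixture)
    probs = np.array([spec.category_mixture[c] for c in categories])
    decoy_names = sorted(refs.decoys)

    reads: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for design in spec.cohort:
        sid = f"{design.tissue}_{design.donor_id}_{design.prep_kit}"
        sample_reads: list[tuple[str, str]] = []
        for i in range(design.depth):
            rid = f"{sid}_r{i + 1}"
            if decoy_names and rng.random() < spec.decoy_fraction:
                dname = str(rng.choice(decoy_names))
                seq = refs.decoys[dname]
                truth_rows.append(
                    dict(read_id=rid, sample_id=sid, hairpin_id=dname, arm="-",
                         start=0, end=0, substitutions="", nta_seq="",
                         category="decoy", name="", is_decoy=True)
                )
            else:
                hid = str(rng.choice(hairpin_ids))
                hp = refs.hairpins[hid]
                if hid in acpre:
                    arm = "5p"
                elif hid in switch:
                    p5 = (
                        1.0 - spec.switch_bias
                        if design.tissue in spec.switch_tissues
                        else spec.switch_bias
                    )
                    arm = "5p" if rng.random() < p5 else "3p"
                else:
                    arm = "5p" if rng.random() < spec.arm_bias else "3p"
                ann = ann_by[(hid, arm)]
                for _ in range(50):
                    if (hid, arm) in orphan:
                        cat = "start_only"
                        start, end, subs, nta = ann.start + 1, ann.end, (), ""
                        if end - start + 1 < spec.min_tag_len:
                            start = ann.start - 1  # keep >= min length
                            cat = "start_only"
                    elif hid in acpre:
                        if rng.random() < spec.acpre_ext_fraction:
                            de = int(
                                rng.integers(*spec.acpre_ext_range, endpoint=True)
                            )
                            cat = "end_only"
                            start, end, subs, nta = ann.start, ann.end + de, (), ""
                        else:
                            cat = "canonical"
                            start, end, subs, nta = ann.start, ann.end, (), ""
                    else:
                        cat = str(rng.choice(categories, p=probs))
                        if cat == "canonical":
                            start, end, subs, nta = ann.start, ann.end, (), ""
                        else:
                            start, end, subs, nta = _draw_variant(
                                rng, hp, ann, cat, spec
                            )
                    core = _templated_seq(hp, start, end, subs)
                    if checker.unique(core, hid, start, len(subs)):
                        break
                else:
                    raise RuntimeError(
                        f"could not realize an unambiguous {cat} read on {hid}"
                    )
                feats = IsomiRFeatures(
                    delta_start=start - ann.start,
                    delta_end=end - ann.end,
                    substitutions=subs,
                    nta_seq=nta,
                )
                seq = core + nta
                truth_rows.append(
                    dict(
                        read_id=rid, sample_id=sid, hairpin_id=hid, arm=arm,
                        start=start, end=end,
                        substitutions=";".join(f"{p}:{r}>{a}" for p, r, a in subs),
                        nta_seq=nta, category=classify(feats),
                        name=render_name(feats, ann), is_decoy=False,
                    )
                )
            seq = _inject_errors(rng, seq, spec.error_rate)
            if rng.random() < spec.adaptor_read_through:
                seq = seq + spec.adaptor_seq
            sample_reads.append((rid, seq))
        reads[sid] = sample_reads
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample_id", "hairpin_id", "arm", "start", "end",
                 "substitutions", "nta_seq", "category", "name", "is_decoy"],
    )
    return reads, truth


def sample_sheet(spec: SimSpec) -> list[SampleMeta]:
    return [
        SampleMeta(
            f"{d.tissue}_{d.donor_id}_{d.prep_kit}", d.tissue, d.donor_id, d.prep_kit
        )
        for d in spec.cohort
    ]


@dataclass
class SimResult:
    spec: SimSpec
    references: References
    samples: list[SampleMeta]
    reads: dict[str, list[tuple[str, str]]]
    truth: pd.DataFrame


def simulate_cohort(spec: SimSpec, out_dir: str | Path | None = None) -> SimResult:
    """Full fixture: references, sample sheet, reads and truth.

    When ``out_dir`` is given, writes references.fasta, annotations.tsv,
    decoys.fasta, samples.tsv, reads/<sample>.fastq, truth.tsv, the spec as
    simspec.yaml, and a manifest with the seed and file checksums.
    """
    refs = make_references(spec)
    reads, truth = simulate_reads(spec, refs)
    samples = sample_sheet(spec)
    result = SimResult(spec, refs, samples, reads, truth)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "reads").mkdir(parents=True, exist_ok=True)
        write_hairpin_fasta(refs.hairpins, out / "references.fasta")
        write_annotations(refs.annotations, out / "annotations.tsv")
        with open(out / "decoys.fasta", "w") as fh:
            for name, seq in refs.decoys.items():
                fh.write(f">{name}\n{seq}\n")
        write_sample_sheet(samples, out / "samples.tsv")
        for sid, rs in reads.items():
            with open(out / "reads" / f"{sid}.fastq", "w") as fh:
                for rid, seq in rs:
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        spec.to_yaml(out / "simspec.yaml")
        _write_manifest(out, spec.seed)
    return result


def _write_manifest(out: Path, seed: int) -> None:
    lines = [f"seed\t{seed}"]
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.tsv":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            lines.append(f"{path.relative_to(out)}\t{digest}")
    (out / "manifest.tsv").write_text("\n".join(lines) + "\n")
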