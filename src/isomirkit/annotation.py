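"""IsomiR featurization, classification, and machine-parsable naming.

Every aligned tag is described relative to the canonical mature annotation
on its hairpin arm by four features: the start offset, the templated end
offset, the substitution count, and the 3' non-templated addition (NTA).
The feature vector maps onto exactly one of seven mutually exclusive
categories, and onto a name of the form::

    <arm_name>|{<label>}|<start>_<end>|<modifiers>

where the label is the canonical mature name for canonical tags and the
literal ``isomiR`` otherwise, the coordinate block is the 1-based inclusive
hairpin span of the templated alignment, and the modifiers are
``sub.<pos>.<ref>><alt>`` / ``add.<pos>.<nt>`` descriptors sorted by
position. ``hsa-miR-143-3p|{hsa-miR-143}|60_80|`` names a canonical tag;
``hsa-miR-143-3p|{isomiR}|62_80|sub.77.G>A`` an isomiR starting two bases
downstream with one substitution. The parser also accepts the spaced
``G > A`` dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from isomirkit.alignment import AlignedTag, Placement
from isomirkit.reference_io import MatureAnnotation

CATEGORIES = (
    "canonical",
    "start_only",
    "end_only",
    "substitution_only",
    "shifted",
    "nta3",
    "mixed",
)


@dataclass(frozen=True)
class IsomiRFeatures:
    """Offsets of a placed tag relative to its canonical mature.

    ``delta_start``/``delta_end`` are signed hairpin-coordinate offsets of
    the templated span (positive = downstream); ``substitutions`` holds the
    (hairpin_pos, ref, alt) triples.
    """

    delta_start: int
    delta_end: int
    substitutions: tuple[tuple[int, str, str], ...]
    nta_seq: str

    @property
    def n_sub(self) -> int:
        return len(self.substitutions)

    @property
    def nta_len(self) -> int:
        return len(self.nta_seq)


class NameError_(ValueError):
    """IsomiR name outside the grammar."""


@dataclass(frozen=True)
class IsomiRName:
    """Structured form of an isomiR name.

    ``modifiers`` are canonical (unspaced) descriptor strings sorted by
    position.
    """

    arm_name: str
    label: str
    start: int
    end: int
    modifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise NameError_(f"start {self.start} > end {self.end}")

    def render(self) -> str:
        return f"{self.arm_name}|{{{self.label}}}|{self.start}_{self.end}|" + ";".join(
            self.modifiers
        )


def assign_arm(
    placement: Placement, annotations: Sequence[MatureAnnotation]
) -> MatureAnnotation | None:
    """Pick the mature annotation whose span overlaps the placement most.

    Ties go to the 5p arm. Returns None (orphan-side: the tag lies wholly
    outside both mature spans, e.g. in the loop) when neither overlaps.
    """
    anns = [a for a in annotations if a.hairpin_id == placement.hairpin_id]
    if not anns:
        raise ValueError(f"hairpin {placement.hairpin_id!r} has no annotations")
    best: MatureAnnotation | None = None
    best_overlap = 0
    for ann in sorted(anns, key=lambda a: a.arm):  # "3p" < "5p"; 5p wins ties below
        overlap = min(placement.end, ann.end) - max(placement.start, ann.start) + 1
        if overlap > best_overlap or (
            overlap == best_overlap and overlap > 0 and ann.arm == "5p"
        ):
            best, best_overlap = ann, overlap
    return best


def featurize(
    aligned: AlignedTag | Placement,
    annotation: MatureAnnotation,
    nta_seq: str | None = None,
) -> IsomiRFeatures:
    """Feature vector of one placement relative to one mature annotation.

    Accepts an :class:`AlignedTag` (single placement; NTA taken from it) or
    a bare :class:`Placement` plus an explicit ``nta_seq``. Multi-placement
    tags are featurized per placement by the pipeline.
    """
    if isinstance(aligned, AlignedTag):
        if len(aligned.placements) != 1 and nta_seq is None:
            raise ValueError("featurize one placement at a time for multi-mapped tags")
        placement = aligned.placements[0]
        nta = aligned.nta_seq
    else:
        placement = aligned
        nta = nta_seq or ""
    if placement.hairpin_id != annotation.hairpin_id:
        raise ValueError("placement and annotation are on different hairpins")
    return IsomiRFeatures(
        delta_start=placement.start - annotation.start,
        delta_end=placement.end - annotation.end,
        substitutions=placement.substitutions,
        nta_seq=nta,
    )


def classify(features: IsomiRFeatures) -> str:
    """Assign exactly one of the seven mutually exclusive categories.

    Start/end offsets, substitutions and 3' NTA each define a pure class
    when they occur alone; equal non-zero start and end offsets (length
    preserved) are the shifted class; any combination is mixed.
    """
    ds, de = features.delta_start, features.delta_end
    ns, na = features.n_sub, features.nta_len
    if ds == 0 and de == 0 and ns == 0 and na == 0:
        return "canonical"
    if de == 0 and ns == 0 and na == 0:
        return "start_only"
    if ds == 0 and ns == 0 and na == 0:
        return "end_only"
    if ds == 0 and de == 0 and na == 0:
        return "substitution_only"
    if ds == de and ns == 0 and na == 0:
        return "shifted"
    if ds == 0 and de == 0 and ns == 0:
        return "nta3"
    return "mixed"


def render_name(
    features: IsomiRFeatures,
    annotation: MatureAnnotation,
    category: str | None = None,
) -> str:
    """Render the canonical name string for a classified tag."""
    if category is None:
        category = classify(features)
    start = annotation.start + features.delta_start
    end = annotation.end + features.delta_end
    label = annotation.mature_name if category == "canonical" else "isomiR"
    mods = [f"sub.{pos}.{ref}>{alt}" for pos, ref, alt in features.substitutions]
    mods.extend(
        f"add.{end + 1 + j}.{nt}" for j, nt in enumerate(features.nta_seq)
    )
    mods.sort(key=_modifier_position)
    return IsomiRName(annotation.arm_name, label, start, end, tuple(mods)).render()


_SUB_RE = re.compile(r"^sub\.(\d+)\.([ACGT])\s*>\s*([ACGT])$")
_ADD_RE = re.compile(r"^add\.(\d+)\.([ACGT])$")


def _modifier_position(mod: str) -> int:
    m = _SUB_RE.match(mod) or _ADD_RE.match(mod)
    if not m:
        raise NameError_(f"unrecognized modifier {mod!r}")
    return int(m.group(1))


def parse_name(name: str) -> IsomiRName:
    """Parse a name string (spaced or unspaced substitution dialect).

    Validates the coordinate order, that substitution positions fall inside
    the span, and that NTA positions fall immediately beyond it.
    """
    parts = name.split("|")
    if len(parts) != 4:
        raise NameError_(f"expected 4 '|'-separated fields in {name!r}")
    arm_name, label, coords, mod_field = parts
    if not (label.startswith("{") and label.endswith("}")):
        raise NameError_(f"label must be brace-wrapped in {name!r}")
    label = label[1:-1]
    m = re.match(r"^(\d+)_(\d+)$", coords)
    if not m:
        raise NameError_(f"bad coordinate block {coords!r} in {name!r}")
    start, end = int(m.group(1)), int(m.group(2))
    if start > end:
        raise NameError_(f"start > end in {name!r}")
    modifiers: list[str] = []
    if mod_field.strip():
        for raw in mod_field.split(";"):
            raw = raw.strip()
            sm = _SUB_RE.match(raw)
            am = _ADD_RE.match(raw)
            if sm:
                pos = int(sm.group(1))
                if not (start <= pos <= end):
                    raise NameError_(
                        f"substitution position {pos} outside span {start}_{end}"
                    )
                modifiers.append(f"sub.{pos}.{sm.group(2)}>{sm.group(3)}")
            elif am:
                pos = int(am.group(1))
                if pos <= end:
                    raise NameError_(
                        f"addition position {pos} not beyond span end {end}"
                    )
                modifiers.append(raw)
            else:
                raise NameError_(f"unrecognized modifier {raw!r} in {name!r}")
    modifiers.sort(key=_modifier_position)
    return IsomiRName(arm_name, label, start, end, tuple(modifiers))


def canonical_name(annotation: MatureAnnotation) -> str:
    """The name string of the canonical tag for a mature annotation."""
    return IsomiRName(
        annotation.arm_name,
        annotation.mature_name,
        annotation.start,
        annotation.end,
    ).render()


def annotate_aligned_tags(
    aligned: Iterable[AlignedTag],
    annotations: Sequence[MatureAnnotation],
) -> pd.DataFrame:
    """Run arm assignment, featurization, classification and naming.

    Returns one row per (tag, placement) with columns sample_id, name,
    category, hairpin_id, arm, weight, multiplicity, mass (= multiplicity x
    weight). Orphan-side placements (no overlap with either mature span)
    are kept with category ``orphan_side`` and an arm of ``-`` so that tag
    mass is still accounted for; they carry no isomiR name.
    """
    by_hairpin: dict[str, list[MatureAnnotation]] = {}
    for a in annotations:
        by_hairpin.setdefault(a.hairpin_id, []).append(a)
    rows = []
    for at in aligned:
        for p in at.placements:
            ann = assign_arm(p, by_hairpin.get(p.hairpin_id, ()) ) if p.hairpin_id in by_hairpin else None
            mass = at.tag.multiplicity * at.weight_per_placement
            if ann is None:
                rows.append(
                    dict(
                        sample_id=at.tag.sample_id, name="", category="orphan_side",
                        hairpin_id=p.hairpin_id, arm="-", weight=at.weight_per_placement,
                        multiplicity=at.tag.multiplicity, mass=mass,
                    )
                )
                continue
            feats = featurize(p, ann, nta_seq=at.nta_seq)
            cat = classify(feats)
            rows.append(
                dict(
                    sample_id=at.tag.sample_id,
                    name=render_name(feats, ann, cat),
                    category=cat,
                    hairpin_id=p.hairpin_id,
                    arm=ann.arm,
                    weight=at.weight_per_placement,
                    multiplicity=at.tag.multiplicity,
                    mass=mass,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "name", "category", "hairpin_id", "arm",
            "weight", "multiplicity", "mass",
        ],
    )


def flag_orphans(
    detected: pd.DataFrame,
    annotations: Sequence[MatureAnnotation],
) -> set[str]:
    """IsomiRs whose parent arm's canonical form is detected in no sample.

    ``detected`` is a feature x sample table whose truthy entries mean the
    feature was detected in that sample (tpm above threshold, typically).
    Orphans can arise from mis-annotated matures and are excluded from
    category statistics when requested.
    """
    canon_by_arm = {a.arm_name: canonical_name(a) for a in annotations}
    present = detected.astype(bool)
    detected_anywhere = set(present.index[present.any(axis=1)])
    orphans: set[str] = set()
    for name in detected_anywhere:
        rec = parse_name(name)
        if rec.label != "isomiR":
            continue
        canon = canon_by_arm.get(rec.arm_name)
        if canon is None or canon not in detected_anywhere:
            orphans.add(name)
    return orphans
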