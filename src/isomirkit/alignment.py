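"""Substitution-only alignment of small-RNA tags to hairpin references.

Two complementary strategies are provided:

* **recursive mapping** — try the tag at full length, and while nothing
  places, trim bases off the 3' end and retry down to a minimum length.
  Maximally sensitive for expression quantification, but the reported 3'
  end is a lower bound, not the captured end.
* **adaptor-trimmed mapping** — locate and strip the 3' sequencing adaptor
  first, so the exact 3' end of the captured insert is known, then place
  the whole insert in a single pass after peeling any 3' non-templated
  addition (NTA). Required for isomiR end-site calls.

Placements are substitution-bounded Hamming matches: no insertions or
deletions, at most ``max_sub`` mismatches (default 2), minimum tag length
20 nt. Tags matching several references equally well keep all equal-best
placements with fractional weight 1/k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from isomirkit.reference_io import Hairpin, Tag


@dataclass(frozen=True)
class AlignerParams:
    """Alignment parameters.

    ``max_sub`` and ``min_len`` are the substitution budget and minimum
    aligned length; ``trim_step`` is how many 3' bases the recursive
    strategy removes per retry; ``nta_max`` bounds the 3' non-templated
    addition length; the ``adaptor_*`` fields control 3' adaptor stripping.
    """

    max_sub: int = 2
    min_len: int = 20
    trim_step: int = 1
    nta_max: int = 5
    adaptor_seq: str = ""
    adaptor_min_overlap: int = 5
    adaptor_max_mismatch_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.max_sub < 0 or self.min_len < 1 or self.trim_step < 1:
            raise ValueError("invalid aligner parameters")
        if not (0 <= self.adaptor_max_mismatch_frac < 0.5):
            raise ValueError("adaptor_max_mismatch_frac must be in [0, 0.5)")


@dataclass(frozen=True)
class Placement:
    """A templated alignment of a tag (or tag core) on one hairpin.

    Coordinates are 1-based inclusive; ``substitutions`` holds
    ``(hairpin_pos, ref_base, tag_base)`` triples in ascending position.
    """

    hairpin_id: str
    start: int
    end: int
    substitutions: tuple[tuple[int, str, str], ...]

    @property
    def n_sub(self) -> int:
        return len(self.substitutions)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AlignedTag:
    """A tag together with its equal-best placement set."""

    tag: Tag
    strategy: str  # "recursive" | "adaptor_trimmed"
    aligned_len: int
    placements: tuple[Placement, ...]
    nta_seq: str = ""

    def __post_init__(self) -> None:
        if not self.placements:
            raise ValueError("AlignedTag requires at least one placement")
        n_subs = {p.n_sub for p in self.placements}
        lens = {p.length for p in self.placements}
        if len(n_subs) != 1 or lens != {self.aligned_len}:
            raise ValueError("placements must share n_sub and aligned_len")

    @property
    def weight_per_placement(self) -> float:
        return 1.0 / len(self.placements)


@dataclass(frozen=True)
class MapOutcome:
    """Result of running one strategy on one tag."""

    status: str  # mapped | unmapped_short | unmapped_no_placement | no_adaptor
    aligned: AlignedTag | None = None

    @property
    def mapped(self) -> bool:
        return self.status == "mapped"


@lru_cache(maxsize=4096)
def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming_scan(tag_seq: str, hairpin: Hairpin, max_sub: int) -> list[Placement]:
    """All gapless placements of ``tag_seq`` on ``hairpin`` within ``max_sub``.

    Every offset with Hamming distance <= max_sub is returned, sorted by
    (n_sub, start). A tag longer than the hairpin yields an empty list.
    """
    n = len(tag_seq)
    if n == 0 or n > hairpin.length:
        return []
    hp = _encode(hairpin.sequence)
    tg = _encode(tag_seq)
    windows = sliding_window_view(hp, n)
    mism = (windows != tg).sum(axis=1)
    hits = np.nonzero(mism <= max_sub)[0]
    placements = []
    for off in hits:
        subs = tuple(
            (int(off + j + 1), hairpin.sequence[off + j], tag_seq[j])
            for j in np.nonzero(windows[off] != tg)[0]
        )
        placements.append(
            Placement(hairpin.id, int(off) + 1, int(off) + n, subs)
        )
    placements.sort(key=lambda p: (p.n_sub, p.start))
    return placements


def trim_adaptor(read_seq: str, params: AlignerParams) -> tuple[str, bool]:
    """Strip the 3' sequencing adaptor from a read.

    Scans 5'->3' for the first position where a prefix of the adaptor
    matches the remainder of the read with overlap >= ``adaptor_min_overlap``
    and mismatch fraction <= ``adaptor_max_mismatch_frac``; returns the read
    prefix before that position. The flag reports whether an adaptor was
    found; the read is returned unchanged when it was not.
    """
    adaptor = params.adaptor_seq
    if not adaptor:
        raise ValueError("adaptor_seq is not configured")
    n = len(read_seq)
    for i in range(0, n - params.adaptor_min_overlap + 1):
        overlap = min(len(adaptor), n - i)
        window = read_seq[i : i + overlap]
        mismatches = sum(a != b for a, b in zip(window, adaptor))
        if mismatches <= params.adaptor_max_mismatch_frac * overlap:
            return read_seq[:i], True
    return read_seq, False


def resolve_multimap(placements: Sequence[Placement]) -> tuple[Placement, ...]:
    """Reduce a placement list to the minimal-substitution equal-best set.

    The survivors are ordered by (hairpin_id, start); downstream each
    carries fractional weight 1/k so total tag mass is conserved.
    """
    if not placements:
        raise ValueError("empty placement list")
    best = min(p.n_sub for p in placements)
    kept = [p for p in placements if p.n_sub == best]
    kept.sort(key=lambda p: (p.hairpin_id, p.start))
    return tuple(kept)


def recursive_map(
    tag: Tag | str,
    hairpins: Mapping[str, Hairpin],
    params: AlignerParams = AlignerParams(),
) -> MapOutcome:
    """Recursive-trimming alignment of one tag against all hairpins.

    Tries the full tag; while nothing places and the next length is still
    >= ``min_len``, trims ``trim_step`` bases from the 3' end and retries.
    On success returns the equal-best placement set at the first (longest)
    successful length.
    """
    if isinstance(tag, str):
        tag = Tag(tag, 1, "?")
    seq = tag.sequence
    if len(seq) < params.min_len:
        return MapOutcome("unmapped_short")
    length = len(seq)
    while length >= params.min_len:
        sub = seq[:length]
        hits: list[Placement] = []
        for hp in hairpins.values():
            hits.extend(hamming_scan(sub, hp, params.max_sub))
        if hits:
            placements = resolve_multimap(hits)
            return MapOutcome(
                "mapped",
                AlignedTag(tag, "recursive", length, placements, nta_seq=""),
            )
        length -= params.trim_step
    return MapOutcome("unmapped_no_placement")


def _suffix_is_nta(
    tag_seq: str, k: int, placement: Placement, hairpin: Hairpin
) -> bool:
    # the k-base 3' suffix is non-templated iff every suffix base either
    # falls past the hairpin 3' end or differs from the hairpin base there
    for j in range(k):
        pos = placement.end + 1 + j  # 1-based hairpin position
        if pos <= hairpin.length and hairpin.sequence[pos - 1] == tag_seq[len(tag_seq) - k + j]:
            return False
    return True


def extract_nta(
    tag_seq: str,
    hairpin: Hairpin,
    params: AlignerParams = AlignerParams(),
) -> tuple[list[Placement], str] | None:
    """Split an exact-ended tag into a templated core and a 3' NTA suffix.

    Considers suffix lengths 0..nta_max (core length never below min_len).
    A split is valid when the core places within ``max_sub`` and, for a
    non-empty suffix, every suffix base is non-templated (past the hairpin
    end or mismatching). The winning split minimizes (n_sub, suffix length),
    so a fully templated placement beats an NTA call at equal substitution
    cost and terminal mismatches within budget are preferred as
    substitutions only when they cost no more.
    """
    n = len(tag_seq)
    best_key: tuple[int, int] | None = None
    best: tuple[list[Placement], str] | None = None
    for k in range(0, min(params.nta_max, n - params.min_len) + 1):
        core = tag_seq[: n - k]
        placements = hamming_scan(core, hairpin, params.max_sub)
        if not placements:
            continue
        if k > 0:
            placements = [
                p for p in placements if _suffix_is_nta(tag_seq, k, p, hairpin)
            ]
            if not placements:
                continue
        min_sub = min(p.n_sub for p in placements)
        key = (min_sub, k)
        if best_key is None or key < best_key:
            best_key = key
            best = (
                [p for p in placements if p.n_sub == min_sub],
                tag_seq[n - k :] if k else "",
            )
        if best_key == (0, 0):  # cannot be beaten
            break
    return best


def adaptor_trim_map(
    read: Tag | str,
    hairpins: Mapping[str, Hairpin],
    params: AlignerParams,
) -> MapOutcome:
    """Adaptor-trimmed exact-end alignment of one read.

    The adaptor is stripped first; the insert is then placed at its full
    length (no recursive trimming) after peeling any 3' NTA. Reads without
    a recognizable adaptor are unusable by this strategy (they may still
    map recursively).
    """
    if isinstance(read, Tag):
        tag, seq = read, read.sequence
    else:
        tag, seq = Tag(read, 1, "?"), read
    insert, found = trim_adaptor(seq, params)
    if not found:
        return MapOutcome("no_adaptor")
    if len(insert) < params.min_len:
        return MapOutcome("unmapped_short")
    best_key: tuple[int, int] | None = None
    pooled: list[Placement] = []
    nta = ""
    for hp in hairpins.values():
        res = extract_nta(insert, hp, params)
        if res is None:
            continue
        placements, nta_seq = res
        key = (placements[0].n_sub, len(nta_seq))
        if best_key is None or key < best_key:
            best_key, pooled, nta = key, list(placements), nta_seq
        elif key == best_key:
            pooled.extend(placements)
    if not pooled:
        return MapOutcome("unmapped_no_placement")
    placements = resolve_multimap(pooled)
    collapsed = Tag(insert, tag.multiplicity, tag.sample_id)
    return MapOutcome(
        "mapped",
        AlignedTag(
            collapsed,
            "adaptor_trimmed",
            len(insert) - len(nta),
            placements,
            nta_seq=nta,
        ),
    )


def align_all(
    tags: Iterable[Tag],
    hairpins: Mapping[str, Hairpin],
    params: AlignerParams,
    strategy: str = "recursive",
) -> tuple[list[AlignedTag], dict[str, int]]:
    """Align a tag collection with one strategy.

    Returns the mapped tags and a status tally (counting read multiplicity)
    for the run log.
    """
    if strategy == "recursive":
        fn = lambda t: recursive_map(t, hairpins, params)
    elif strategy == "adaptor_trimmed":
        fn = lambda t: adaptor_trim_map(t, hairpins, params)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    mapped: list[AlignedTag] = []
    tally: dict[str, int] = {}
    for tag in tags:
        outcome = fn(tag)
        tally[outcome.status] = tally.get(outcome.status, 0) + tag.multiplicity
        if outcome.aligned is not None:
            mapped.append(outcome.aligned)
    return mapped, tally


# ---------------------------------------------------------------------------
# export

def format_substitutions(placement: Placement) -> str:
    return ";".join(f"{p}:{r}>{a}" for p, r, a in placement.substitutions)


def write_alignments(aligned: Iterable[AlignedTag], path: str | Path) -> None:
    """Write placements as a TSV, one row per (tag, placement)."""
    with open(path, "w") as fh:
        fh.write(
            "tag\tsample_id\tmultiplicity\tstrategy\thairpin_id\tstart\tend\t"
            "n_sub\tsubstitutions\tnta_seq\tweight\n"
        )
        for at in aligned:
            for p in at.placements:
                fh.write(
                    f"{at.tag.sequence}\t{at.tag.sample_id}\t{at.tag.multiplicity}\t"
                    f"{at.strategy}\t{p.hairpin_id}\t{p.start}\t{p.end}\t"
                    f"{p.n_sub}\t{format_substitutions(p)}\t{at.nta_seq}\t"
                    f"{at.weight_per_placement:.6g}\n"
                )


def read_alignments(path: str | Path) -> list[AlignedTag]:
    """Re-load an alignment TSV written by :func:`write_alignments`."""
    import csv

    groups: dict[tuple, list[Placement]] = {}
    meta: dict[tuple, dict] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            subs = tuple(
                (int(p.split(":")[0]),) + tuple(p.split(":")[1].split(">"))
                for p in row["substitutions"].split(";") if p
            )
            key = (row["tag"], row["sample_id"], row["strategy"], row["nta_seq"])
            groups.setdefault(key, []).append(
                Placement(row["hairpin_id"], int(row["start"]), int(row["end"]), subs)
            )
            meta[key] = dict(multiplicity=int(row["multiplicity"]))
    out = []
    for (seq, sid, strategy, nta), placements in groups.items():
        placements.sort(key=lambda p: (p.hairpin_id, p.start))
        out.append(
            AlignedTag(
                Tag(seq, meta[(seq, sid, strategy, nta)]["multiplicity"], sid),
                strategy,
                placements[0].length,
                tuple(placements),
                nta_seq=nta,
            )
        )
    return out


def _md_tag(placement: Placement, hairpin_start: int) -> str:
    # MD string for a gapless alignment: match-run lengths interleaved with
    # the reference base at each substitution
    parts: list[str] = []
    prev = placement.start - 1
    for pos, ref, _alt in placement.substitutions:
        parts.append(str(pos - prev - 1))
        parts.append(ref)
        prev = pos
    parts.append(str(placement.end - prev))
    return "".join(parts)


def write_sam(
    aligned: Iterable[AlignedTag],
    hairpins: Mapping[str, Hairpin],
    path: str | Path,
) -> None:
    """Export placements as SAM with hairpins as reference sequences.

    Substitutions are encoded in the MD tag; an NTA suffix appears as a
    3' soft-clip.
    """
    records = list(aligned)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for hp in hairpins.values():
            fh.write(f"@SQ\tSN:{hp.id}\tLN:{hp.length}\n")
        for i, at in enumerate(records):
            clip = f"{len(at.nta_seq)}S" if at.nta_seq else ""
            cigar = f"{at.aligned_len}M{clip}"
            for p in at.placements:
                fh.write(
                    f"tag{i}\t0\t{p.hairpin_id}\t{p.start}\t255\t{cigar}\t*\t0\t0\t"
                    f"{at.tag.sequence}\t*\tNM:i:{p.n_sub}\tMD:Z:{_md_tag(p, p.start)}\n"
                )
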