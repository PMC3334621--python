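"""Cohort-level analyses: positional profiles, arm switching, ac-pre-miRNA
candidate screening, and paired-condition ablation testing.

Arm switching: for each hairpin and tissue, the 5p and 3p arm tpm totals
give a log2 ratio; a hairpin whose dominant arm differs between tissues
(where both arms clear the noise floor) is a switcher. Star-based naming
breaks down for such hairpins, which motivates fixed 5p/3p naming.

ac-pre-miRNA screening: hairpins matured by AGO2 cleavage followed by 3'
exonucleolytic trimming (the miR-451 route, which bypasses Dicer) leave a
characteristic signature: a highly consistent mature 5' end, near-silence
of the opposite arm, and a substantial trail of templated 3' extensions of
the dominant product. Both arms are screened as the potential dominant arm.

Ablation testing: candidates are validated against a paired wild-type /
AGO2-inactive experiment. The deeper library is resampled without
replacement to the shallower depth, candidate-derived tag mass is compared
by a 2x2 Pearson chi-square, and each candidate is classed by how far its
canonical product falls in the mutant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from isomirkit.alignment import AlignedTag
from isomirkit.annotation import assign_arm, canonical_name, parse_name
from isomirkit.reference_io import Hairpin, MatureAnnotation, SampleMeta, Tag

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PositionalProfile:
    """Weighted per-position base counts for one hairpin.

    ``matrix`` has one row per hairpin position 1..L plus ``n_beyond``
    beyond-end bins for non-templated additions, and one column per base.
    ``start_hist`` / ``end_hist`` are per-arm histograms of the tag 5'
    start and templated 3' end positions.
    """

    hairpin_id: str
    length: int
    n_beyond: int
    matrix: np.ndarray  # (length + n_beyond, 4)
    start_hist: dict[str, dict[int, float]]
    end_hist: dict[str, dict[int, float]]

    @property
    def total_mass(self) -> float:
        """Total deposited tag mass (positional mass / positions per tag)."""
        return float(sum(sum(h.values()) for h in self.start_hist.values()))


def build_profile(
    aligned: Iterable[AlignedTag],
    hairpin: Hairpin,
    annotations: Sequence[MatureAnnotation],
    nta_max: int = 5,
) -> PositionalProfile:
    """Accumulate tag mass per hairpin position and per arm.

    Each placement deposits (multiplicity x weight) on its templated
    positions — using the *tag* base, so substitutions show up — and on
    beyond-end bins for NTA bases. The start/end histograms record the
    templated span boundaries under the assigned arm ("-" for loop-only
    placements).
    """
    mat = np.zeros((hairpin.length + nta_max, 4))
    start_hist: dict[str, dict[int, float]] = {"5p": {}, "3p": {}, "-": {}}
    end_hist: dict[str, dict[int, float]] = {"5p": {}, "3p": {}, "-": {}}
    anns = [a for a in annotations if a.hairpin_id == hairpin.id]
    for at in aligned:
        for p in at.placements:
            if p.hairpin_id != hairpin.id:
                continue
            mass = at.tag.multiplicity * at.weight_per_placement
            sub_at = {pos: alt for pos, _ref, alt in p.substitutions}
            for pos in range(p.start, p.end + 1):
                base = sub_at.get(pos, hairpin.sequence[pos - 1])
                mat[pos - 1, _BASE_IDX[base]] += mass
            for j, nt in enumerate(at.nta_seq):
                row = p.end + j  # 0-based row index for position end+1+j
                if row < mat.shape[0]:
                    mat[row, _BASE_IDX[nt]] += mass
            ann = assign_arm(p, anns) if anns else None
            arm = ann.arm if ann is not None else "-"
            start_hist[arm][p.start] = start_hist[arm].get(p.start, 0.0) + mass
            end_hist[arm][p.end] = end_hist[arm].get(p.end, 0.0) + mass
    return PositionalProfile(hairpin.id, hairpin.length, nta_max, mat, start_hist, end_hist)


def profiles_by_tissue(
    aligned: Iterable[AlignedTag],
    hairpins: Mapping[str, Hairpin],
    annotations: Sequence[MatureAnnotation],
    samples: Sequence[SampleMeta],
    nta_max: int = 5,
) -> dict[str, dict[str, PositionalProfile]]:
    """Per-tissue, per-hairpin positional profiles."""
    tissue_of = {s.sample_id: s.tissue for s in samples}
    by_tissue: dict[str, list[AlignedTag]] = {}
    for at in aligned:
        by_tissue.setdefault(tissue_of[at.tag.sample_id], []).append(at)
    out: dict[str, dict[str, PositionalProfile]] = {}
    for tissue, tags in by_tissue.items():
        touched = {p.hairpin_id for at in tags for p in at.placements}
        out[tissue] = {
            hid: build_profile(tags, hairpins[hid], annotations, nta_max)
            for hid in sorted(touched)
        }
    return out


def _feature_arm_map(
    features: Iterable[str], annotations: Sequence[MatureAnnotation]
) -> dict[str, MatureAnnotation]:
    by_arm_name = {a.arm_name: a for a in annotations}
    out = {}
    for name in features:
        ann = by_arm_name.get(parse_name(name).arm_name)
        if ann is not None:
            out[name] = ann
    return out


def arm_dominance_table(
    tpm_matrix: pd.DataFrame,
    annotations: Sequence[MatureAnnotation],
    samples: Sequence[SampleMeta],
    noise_floor: float = 10.0,
) -> pd.DataFrame:
    """Per (hairpin, tissue) arm totals, dominance and eligibility.

    Arm totals are the sum of feature tpm on the arm, averaged over the
    tissue's samples. A row is eligible when both arm totals reach the
    noise floor; the log2 ratio is NaN when either arm is silent.
    """
    ann_of = _feature_arm_map(tpm_matrix.index, annotations)
    by_tissue: dict[str, list[str]] = {}
    for s in samples:
        by_tissue.setdefault(s.tissue, []).append(s.sample_id)
    hairpins = sorted({a.hairpin_id for a in annotations})
    rows = []
    for hid in hairpins:
        feats_5p = [f for f, a in ann_of.items() if a.hairpin_id == hid and a.arm == "5p"]
        feats_3p = [f for f, a in ann_of.items() if a.hairpin_id == hid and a.arm == "3p"]
        for tissue, sids in sorted(by_tissue.items()):
            t5 = float(tpm_matrix.loc[feats_5p, sids].sum(axis=0).mean()) if feats_5p else 0.0
            t3 = float(tpm_matrix.loc[feats_3p, sids].sum(axis=0).mean()) if feats_3p else 0.0
            ratio = math.log2(t5 / t3) if t5 > 0 and t3 > 0 else float("nan")
            rows.append(
                dict(
                    hairpin_id=hid, tissue=tissue, tpm_5p=t5, tpm_3p=t3,
                    log2_ratio=ratio,
                    dominant="5p" if t5 > t3 else "3p",
                    eligible=bool(t5 >= noise_floor and t3 >= noise_floor),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["hairpin_id", "tissue", "tpm_5p", "tpm_3p",
                 "log2_ratio", "dominant", "eligible"],
    )


def detect_arm_switching(dominance: pd.DataFrame) -> pd.DataFrame:
    """Hairpins whose dominant arm is not constant across eligible tissues.

    Only hairpins with >= 2 eligible tissues are assessable. The report
    lists the minority-arm tissues for each switched hairpin.
    """
    rows = []
    for hid, grp in dominance[dominance["eligible"]].groupby("hairpin_id"):
        if len(grp) < 2:
            continue
        doms = grp["dominant"]
        switched = doms.nunique() > 1
        minority = ""
        if switched:
            major = doms.mode().iloc[0]
            minority = ",".join(sorted(grp.loc[doms != major, "tissue"]))
        rows.append(
            dict(hairpin_id=hid, n_eligible_tissues=len(grp),
                 switched=switched, minority_tissues=minority)
        )
    return pd.DataFrame(
        rows, columns=["hairpin_id", "n_eligible_tissues", "switched", "minority_tissues"]
    )


@dataclass(frozen=True)
class AcPreThresholds:
    """Operating thresholds of the ac-pre-miRNA candidate screen.

    ``modal5_min``: minimum fraction of dominant-arm mass sharing the modal
    5' start; ``ext_fraction_min`` and ``n_distinct_ext_min``: minimum mass
    fraction and distinct end positions of templated 3' extensions at
    least ``ext_min_nt`` beyond the canonical end; ``noise_floor``: maximum
    tpm tolerated on the opposite arm.
    """

    modal5_min: float = 0.9
    ext_fraction_min: float = 0.1
    n_distinct_ext_min: int = 3
    ext_min_nt: int = 2
    noise_floor: float = 10.0


def find_acpre_candidates(
    profiles: Mapping[str, Mapping[str, PositionalProfile]],
    tpm_matrix: pd.DataFrame,
    annotations: Sequence[MatureAnnotation],
    samples: Sequence[SampleMeta],
    thresholds: AcPreThresholds = AcPreThresholds(),
) -> pd.DataFrame:
    """Screen every (hairpin, arm) for the ac-pre-miRNA signature.

    Evaluated per tissue, restricted to tissues whose samples span at
    least two prep kits. A (hairpin, arm) is a candidate when in at least
    one eligible tissue all three criteria hold: modal-5'-start fraction,
    opposite-arm silence, and the 3'-extension trail. Returns one row per
    (hairpin, arm, tissue) with the criterion values and flags; overall
    candidates are rows aggregated by ``pass_all``.
    """
    ann_by = {(a.hairpin_id, a.arm): a for a in annotations}
    ann_of_feature = _feature_arm_map(tpm_matrix.index, annotations)
    kits_by_tissue: dict[str, set[str]] = {}
    sids_by_tissue: dict[str, list[str]] = {}
    for s in samples:
        kits_by_tissue.setdefault(s.tissue, set()).add(s.prep_kit)
        sids_by_tissue.setdefault(s.tissue, []).append(s.sample_id)
    eligible_tissues = sorted(t for t, k in kits_by_tissue.items() if len(k) >= 2)
    rows = []
    for tissue in eligible_tissues:
        for hid, prof in sorted(profiles.get(tissue, {}).items()):
            for arm in ("5p", "3p"):
                ann = ann_by.get((hid, arm))
                if ann is None:
                    log.warning("hairpin %s has no %s annotation; skipped", hid, arm)
                    continue
                starts = prof.start_hist.get(arm, {})
                ends = prof.end_hist.get(arm, {})
                arm_mass = sum(starts.values())
                if arm_mass == 0:
                    continue
                modal5 = max(starts.values()) / arm_mass
                opp = "3p" if arm == "5p" else "5p"
                opp_feats = [
                    f for f, a in ann_of_feature.items()
                    if a.hairpin_id == hid and a.arm == opp
                ]
                sids = sids_by_tissue[tissue]
                opp_max = (
                    float(tpm_matrix.loc[opp_feats, sids].sum(axis=0).max())
                    if opp_feats else 0.0
                )
                ext_cut = ann.end + thresholds.ext_min_nt
                ext_mass = sum(m for pos, m in ends.items() if pos >= ext_cut)
                ext_fraction = ext_mass / arm_mass
                n_ext = sum(1 for pos, m in ends.items() if pos >= ext_cut and m > 0)
                pass_modal5 = modal5 >= thresholds.modal5_min
                pass_opp = opp_max < thresholds.noise_floor
                pass_ext = (
                    ext_fraction >= thresholds.ext_fraction_min
                    and n_ext >= thresholds.n_distinct_ext_min
                )
                rows.append(
                    dict(
                        hairpin_id=hid, dominant_arm=arm, tissue=tissue,
                        modal5_fraction=modal5, opposite_arm_max_tpm=opp_max,
                        ext_fraction=ext_fraction, n_distinct_ext_ends=n_ext,
                        pass_modal5=pass_modal5, pass_opposite=pass_opp,
                        pass_ext=pass_ext,
                        pass_all=bool(pass_modal5 and pass_opp and pass_ext),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["hairpin_id", "dominant_arm", "tissue", "modal5_fraction",
                 "opposite_arm_max_tpm", "ext_fraction", "n_distinct_ext_ends",
                 "pass_modal5", "pass_opposite", "pass_ext", "pass_all"],
    )


def candidate_set(acpre_table: pd.DataFrame) -> set[tuple[str, str]]:
    """(hairpin, dominant arm) pairs passing all criteria in >= 1 tissue."""
    if acpre_table.empty:
        return set()
    passed = acpre_table[acpre_table["pass_all"]]
    return set(zip(passed["hairpin_id"], passed["dominant_arm"]))


def resample_to_depth(
    tags: Sequence[Tag], target_depth: int, seed: int
) -> list[Tag]:
    """Uniform subsampling of reads without replacement to a target depth.

    Draws from the expanded read multiset (each tag contributing
    ``multiplicity`` reads) via a multivariate hypergeometric draw, so each
    tag's expected retained count is multiplicity x target/depth.
    """
    depth = sum(t.multiplicity for t in tags)
    if target_depth > depth:
        raise ValueError(f"target depth {target_depth} exceeds library depth {depth}")
    if target_depth == depth:
        return list(tags)
    rng = np.random.default_rng(seed)
    mult = np.array([t.multiplicity for t in tags])
    drawn = rng.multivariate_hypergeometric(mult, target_depth)
    return [
        Tag(t.sequence, int(k), t.sample_id)
        for t, k in zip(tags, drawn) if k > 0
    ]


def chi_square_2x2(a: float, b: float, c: float, d: float) -> tuple[float, int, float]:
    """Pearson chi-square for a 2x2 table, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); p is the upper tail of
    the chi-square distribution with 1 df.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m <= 0 for m in margins):
        raise ValueError("degenerate margins in 2x2 table")
    stat = n * (a * d - b * c) ** 2 / math.prod(margins)
    return float(stat), 1, float(chi2_dist.sf(stat, 1))


@dataclass(frozen=True)
class AblationResult:
    """Group-level candidate mass comparison between conditions."""

    feature_group: str
    wt_mass: float
    mut_mass: float
    reduction_fraction: float
    chi2: float
    df: int
    p: float


def ablation_report(
    wt_counts: pd.Series,
    mut_counts: pd.Series,
    candidates: Iterable[tuple[str, str]],
    annotations: Sequence[MatureAnnotation],
    reduction_threshold: float = 0.80,
) -> tuple[AblationResult, pd.DataFrame]:
    """Compare candidate-derived expression between wild-type and mutant.

    ``wt_counts`` / ``mut_counts`` are per-feature mass vectors (mutant
    already resampled to wild-type depth). The group test is a 2x2
    chi-square of candidate vs non-candidate mass across conditions. Each
    candidate is classed as ``complete_ablation`` (no canonical mass left),
    ``strong_reduction`` (canonical reduction > threshold),
    ``isomiR_support`` (arm isomiR mass below threshold x wild-type), else
    ``unsupported``. Candidates absent from both conditions are excluded.
    """
    ann_by = {(a.hairpin_id, a.arm): a for a in annotations}
    all_feats = wt_counts.index.union(mut_counts.index)
    wt = wt_counts.reindex(all_feats, fill_value=0.0)
    mut = mut_counts.reindex(all_feats, fill_value=0.0)
    ann_of_feature = _feature_arm_map(all_feats, annotations)
    cand = sorted(set(candidates))
    cand_feats = [
        f for f, a in ann_of_feature.items() if (a.hairpin_id, a.arm) in set(cand)
    ]
    a_ = float(wt[cand_feats].sum())
    b_ = float(wt.sum() - a_)
    c_ = float(mut[cand_feats].sum())
    d_ = float(mut.sum() - c_)
    stat, df, p = chi_square_2x2(a_, b_, c_, d_)
    group = AblationResult(
        "ac_pre_candidates", a_, c_,
        1.0 - c_ / a_ if a_ > 0 else float("nan"), stat, df, p,
    )
    rows = []
    for hid, arm in cand:
        ann = ann_by.get((hid, arm))
        if ann is None:
            log.warning("candidate (%s, %s) has no annotation; excluded", hid, arm)
            continue
        canon = canonical_name(ann)
        arm_feats = [
            f for f, a in ann_of_feature.items()
            if a.hairpin_id == hid and a.arm == arm
        ]
        wt_can = float(wt.get(canon, 0.0))
        mut_can = float(mut.get(canon, 0.0))
        iso_feats = [f for f in arm_feats if f != canon]
        wt_iso = float(wt[iso_feats].sum())
        mut_iso = float(mut[iso_feats].sum())
        if wt_can + mut_can + wt_iso + mut_iso == 0:
            log.warning("candidate (%s, %s) absent from both conditions; excluded",
                        hid, arm)
            continue
        reduction = 1.0 - mut_can / wt_can if wt_can > 0 else float("nan")
        if wt_can > 0 and mut_can == 0:
            support = "complete_ablation"
        elif wt_can > 0 and reduction > reduction_threshold:
            support = "strong_reduction"
        elif wt_iso > 0 and mut_iso < reduction_threshold * wt_iso:
            support = "isomiR_support"
        else:
            support = "unsupported"
        rows.append(
            dict(
                hairpin_id=hid, arm=arm,
                wt_canonical=wt_can, mut_canonical=mut_can,
                reduction_fraction=reduction,
                wt_isomir=wt_iso, mut_isomir=mut_iso,
                support_class=support,
            )
        )
    detail = pd.DataFrame(
        rows,
        columns=["hairpin_id", "arm", "wt_canonical", "mut_canonical",
                 "reduction_fraction", "wt_isomir", "mut_isomir", "support_class"],
    )
    return group, detail


def write_profile_tsv(profile: PositionalProfile, path) -> None:
    """Position-weight table for logo rendering: one row per (position, base)."""
    with open(path, "w") as fh:
        fh.write("hairpin_id\tposition\tbase\tmass\tbeyond_end\n")
        for i in range(profile.matrix.shape[0]):
            pos = i + 1
            beyond = pos > profile.length
            for j, base in enumerate(_BASES):
                m = profile.matrix[i, j]
                if m > 0:
                    fh.write(f"{profile.hairpin_id}\t{pos}\t{base}\t{m:.6g}\t{int(beyond)}\n")
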