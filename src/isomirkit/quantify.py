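"""Count matrices, TMM-corrected tags-per-million, noise floor, filters.

Expression is reported as tags per million (tpm) after correcting each
sample's library size with a trimmed-mean-of-M-values (TMM) scaling factor,
which removes the distortion that strong composition differences between
libraries cause in proportional measures. The minimum level regarded as
genuine expression is derived from decoy alignments: tags from one species
should not align to non-conserved mature miRNAs of distant species, so the
largest decoy tpm observed bounds the noise. Features are further filtered
for robustness: present at >= ``min_tpm`` in every sample of at least one
tissue, detected under at least two library-preparation kits, and (if
requested) not orphans.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from isomirkit.alignment import AlignerParams, hamming_scan, recursive_map
from isomirkit.annotation import parse_name, canonical_name, classify, IsomiRFeatures
from isomirkit.reference_io import Hairpin, SampleMeta, Tag, MatureAnnotation

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Robustness filter settings.

    The tissue rule demands tpm >= ``min_tpm`` in *every* sample of at
    least one tissue; the kit rule demands detection (tpm > 0) in samples
    spanning at least ``min_prep_kits`` distinct library-preparation kits.
    """

    min_tpm: float = 10.0
    min_prep_kits: int = 2
    drop_orphans: bool = True

    def __post_init__(self) -> None:
        if self.min_tpm < 0 or self.min_prep_kits < 1:
            raise ValueError("invalid filter configuration")


@dataclass(frozen=True)
class NormFactors:
    """TMM scaling factors and effective library sizes."""

    reference_sample_id: str
    factors: pd.Series  # f_s, geometric mean 1
    raw_library_sizes: pd.Series
    trim_M: float = 0.30
    trim_A: float = 0.05

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.raw_library_sizes * self.factors


def build_counts(
    annotated: pd.DataFrame, samples: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Pivot annotated tags into a feature x sample count matrix.

    ``annotated`` is the table from
    :func:`isomirkit.annotation.annotate_aligned_tags`; entries are the
    summed (multiplicity x weight) mass per isomiR name, so multi-mapped
    tags contribute fractional counts and total mass is conserved.
    Orphan-side rows (no name) are excluded.
    """
    sample_ids = [s.sample_id for s in samples]
    unknown = set(annotated["sample_id"]) - set(sample_ids)
    if unknown:
        raise ValueError(f"unknown sample ids in annotation table: {sorted(unknown)}")
    named = annotated[annotated["name"] != ""]
    if named.empty:
        return pd.DataFrame(index=pd.Index([], name="name"), columns=sample_ids, dtype=float)
    mat = (
        named.pivot_table(index="name", columns="sample_id", values="mass",
                          aggfunc="sum", fill_value=0.0)
        .reindex(columns=sample_ids, fill_value=0.0)
        .sort_index()
    )
    mat.columns.name = "sample_id"
    return mat.astype(float)


def _choose_reference(counts: pd.DataFrame, lib_sizes: pd.Series) -> str:
    # sample whose upper-quartile count fraction is closest to the mean of
    # those fractions across samples
    f75 = counts.quantile(0.75) / lib_sizes
    return (f75 - f75.mean()).abs().idxmin()


def tmm_factors(
    counts: pd.DataFrame,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    reference: str | None = None,
    min_shared: int = 20,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors.

    For each sample s against the reference r, over features positive in
    both: M_g = log2((x_gs/N_s)/(x_gr/N_r)) and A_g = 0.5 log2((x_gs/N_s)
    (x_gr/N_r)); the upper and lower ``trim_M`` of M and ``trim_A`` of A are
    jointly discarded and f_s = 2^(sum w_g M_g / sum w_g) with precision
    weights w_g = 1 / ((N_s - x_gs)/(N_s x_gs) + (N_r - x_gr)/(N_r x_gr)),
    the inverse delta-method variance of M_g. Factors are rescaled to
    geometric mean 1.
    Samples sharing fewer than ``min_shared`` positive features with the
    reference fall back to f = 1 with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        raise ValueError("every sample needs positive mapped mass")
    ref = reference if reference is not None else _choose_reference(counts, lib_sizes)
    if ref not in counts.columns:
        raise ValueError(f"reference sample {ref!r} not in matrix")
    x_r = counts[ref].to_numpy(float)
    n_r = float(lib_sizes[ref])
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        x_s = counts[s].to_numpy(float)
        n_s = float(lib_sizes[s])
        both = (x_s > 0) & (x_r > 0)
        if both.sum() < min_shared:
            log.warning(
                "sample %s shares only %d positive features with reference %s; f=1",
                s, int(both.sum()), ref,
            )
            factors[s] = 1.0
            continue
        xs, xr = x_s[both], x_r[both]
        m = np.log2((xs / n_s) / (xr / n_r))
        a = 0.5 * np.log2((xs / n_s) * (xr / n_r))
        w = 1.0 / ((n_s - xs) / (n_s * xs) + (n_r - xr) / (n_r * xr))
        n = len(m)
        lo_m = math.floor(n * trim_M) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_A) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m)
        ra = rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any() or w[keep].sum() == 0:
            factors[s] = 1.0
            continue
        factors[s] = float(2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))
    f = pd.Series(factors).reindex(counts.columns)
    f /= np.exp(np.mean(np.log(f)))
    return NormFactors(ref, f, lib_sizes.astype(float), trim_M, trim_A)


def tpm(counts: pd.DataFrame, factors: NormFactors | None = None) -> pd.DataFrame:
    """Tags per million, optionally corrected for effective library sizes.

    With ``factors=None`` the raw column sums are used and every column
    sums to exactly 1e6.
    """
    if factors is None:
        sizes = counts.sum(axis=0)
    else:
        sizes = factors.effective_library_sizes.reindex(counts.columns)
    if (sizes <= 0).any() or sizes.isna().any():
        raise ValueError("non-positive or missing library size")
    return counts.div(sizes, axis=1) * 1e6


def _cross_matches(query: str, subject: str, max_sub: int) -> bool:
    # does the shorter sequence place anywhere on the longer within max_sub?
    short, long_ = sorted((query, subject), key=len)
    return bool(hamming_scan(short, Hairpin("x", long_), max_sub))


def decoy_noise_floor(
    tags: Iterable[Tag],
    decoy_matures: Mapping[str, str],
    target_matures: Iterable[str],
    params: AlignerParams,
    raw_library_sizes: Mapping[str, float],
    default_floor: float = 10.0,
) -> int:
    """Noise threshold (tpm) from alignments to cross-species decoy matures.

    Decoys within ``max_sub`` mismatches of any target mature are dropped
    first (they could capture genuine signal). The remaining decoys are
    aligned with the standard recursive parameters; the floor is the
    maximum decoy tpm over all samples, rounded up to an integer. With no
    decoy hits (or no usable decoys) the configured default applies.
    """
    targets = list(target_matures)
    usable: dict[str, Hairpin] = {}
    for name, seq in decoy_matures.items():
        if any(_cross_matches(seq, t, params.max_sub) for t in targets):
            log.warning("decoy %s is within %d mismatches of a target mature; dropped",
                        name, params.max_sub)
            continue
        usable[name] = Hairpin(name, seq)
    if not usable:
        log.warning("no usable decoys; falling back to default floor %g", default_floor)
        return int(math.ceil(default_floor))
    hit_mass: dict[tuple[str, str], float] = {}
    for tag in tags:
        outcome = recursive_map(tag, usable, params)
        if outcome.aligned is not None:
            at = outcome.aligned
            for p in at.placements:
                key = (tag.sample_id, p.hairpin_id)
                hit_mass[key] = hit_mass.get(key, 0.0) + (
                    tag.multiplicity * at.weight_per_placement
                )
    if not hit_mass:
        return int(math.ceil(default_floor))
    max_tpm = max(
        1e6 * mass / raw_library_sizes[sid] for (sid, _d), mass in hit_mass.items()
    )
    return int(math.ceil(max_tpm))


def apply_filters(
    tpm_matrix: pd.DataFrame,
    samples: Sequence[SampleMeta],
    config: FilterConfig = FilterConfig(),
    orphans: set[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the robustness filters; return retained features and a report.

    A feature is retained iff (i) some tissue has tpm >= ``min_tpm`` in
    every one of its samples, (ii) samples with tpm > 0 span at least
    ``min_prep_kits`` distinct prep kits, and (iii) it is not an orphan
    when ``drop_orphans`` is set. The report gives each rule's outcome and
    the first rule that dropped the feature.
    """
    by_tissue: dict[str, list[str]] = {}
    kit_of: dict[str, str] = {}
    for s in samples:
        by_tissue.setdefault(s.tissue, []).append(s.sample_id)
        kit_of[s.sample_id] = s.prep_kit
    for tissue, sids in by_tissue.items():
        if not sids:
            raise ValueError(f"tissue {tissue!r} has no samples")
    orphans = orphans or set()
    rows = []
    retained: list[str] = []
    for feat in tpm_matrix.index:
        vals = tpm_matrix.loc[feat]
        tissue_ok = any(
            all(vals.get(sid, 0.0) >= config.min_tpm for sid in sids)
            for sids in by_tissue.values()
        )
        kits = {kit_of[sid] for sid in tpm_matrix.columns if vals.get(sid, 0.0) > 0}
        kit_ok = len(kits) >= config.min_prep_kits
        orphan = feat in orphans
        orphan_ok = not (config.drop_orphans and orphan)
        keep = tissue_ok and kit_ok and orphan_ok
        dropped_by = ""
        if not keep:
            dropped_by = (
                "tissue_rule" if not tissue_ok
                else "kit_rule" if not kit_ok
                else "orphan_rule"
            )
        rows.append(
            dict(name=feat, tissue_rule=tissue_ok, kit_rule=kit_ok,
                 orphan=orphan, retained=keep, dropped_by=dropped_by)
        )
        if keep:
            retained.append(feat)
    report = pd.DataFrame(
        rows, columns=["name", "tissue_rule", "kit_rule", "orphan", "retained", "dropped_by"]
    )
    return retained, report


def _category_from_name(name: str, ann: MatureAnnotation) -> str:
    rec = parse_name(name)
    subs = tuple(
        (int(m.split(".")[1]),) + tuple(m.split(".")[2].split(">"))
        for m in rec.modifiers if m.startswith("sub.")
    )
    nta = "".join(m.split(".")[2] for m in rec.modifiers if m.startswith("add."))
    feats = IsomiRFeatures(
        delta_start=rec.start - ann.start,
        delta_end=rec.end - ann.end,
        substitutions=subs,
        nta_seq=nta,
    )
    return classify(feats)


def isomir_canonical_ratios(
    tpm_matrix: pd.DataFrame,
    annotations: Sequence[MatureAnnotation],
    samples: Sequence[SampleMeta] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample isomiR / canonical-of-same-arm tpm ratios.

    Ratios with zero canonical tpm are NaN and excluded from the medians.
    Returns the long ratio table and median ratios per category (per
    tissue when a sample sheet is supplied, else overall).
    """
    by_arm = {a.arm_name: a for a in annotations}
    canon_names = {a.arm_name: canonical_name(a) for a in annotations}
    tissue_of = {s.sample_id: s.tissue for s in samples} if samples else None
    rows = []
    for name in tpm_matrix.index:
        rec = parse_name(name)
        if rec.label != "isomiR":
            continue
        ann = by_arm.get(rec.arm_name)
        if ann is None:
            continue
        canon = canon_names[rec.arm_name]
        category = _category_from_name(name, ann)
        for sid in tpm_matrix.columns:
            iso = float(tpm_matrix.at[name, sid])
            can = (
                float(tpm_matrix.at[canon, sid])
                if canon in tpm_matrix.index else 0.0
            )
            ratio = iso / can if can > 0 else float("nan")
            rows.append(
                dict(
                    name=name, category=category, sample_id=sid,
                    tissue=tissue_of.get(sid, "") if tissue_of else "",
                    isomir_tpm=iso, canonical_tpm=can, ratio=ratio,
                )
            )
    ratios = pd.DataFrame(
        rows,
        columns=["name", "category", "sample_id", "tissue",
                 "isomir_tpm", "canonical_tpm", "ratio"],
    )
    if ratios.empty:
        return ratios, pd.DataFrame(columns=["category", "tissue", "median_ratio"])
    group_cols = ["category", "tissue"] if samples else ["category"]
    medians = (
        ratios.dropna(subset=["ratio"])
        .groupby(group_cols)["ratio"].median()
        .reset_index(name="median_ratio")
    )
    if "tissue" not in medians.columns:
        medians["tissue"] = ""
    return ratios, medians[["category", "tissue", "median_ratio"]]


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature x sample matrix as TSV (first column the names)."""
    matrix.to_csv(path, sep="\t", index_label="name")
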