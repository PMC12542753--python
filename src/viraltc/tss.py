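"""TSS detection from stranded coverage step-changes, orientation, and antisense calls.

A transcription start site shows as a sudden, replicate-reproducible rise
in per-base depth.  The detector formalises this as a windowed step-ratio
test: at candidate position p the mean depth over the w bases downstream
(in transcription direction) is compared with the w bases upstream, pooled
at the timepoint of maximal local expression so late transcripts are not
diluted by early zero-coverage samples.  A position is emitted when the
downstream/upstream ratio and absolute downstream depth clear their
thresholds in at least ``replicate_quorum`` replicates at exactly the same
base.

Detected sites are then oriented against the annotation (sense promoter,
internal promoter within a gene, antisense), and genes are called
antisense-dominated when strand-summed antisense coverage exceeds sense
coverage at enough timepoints.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .annotation import AnnotatedFeature, GenomeAnnotation, Strand
from .coverage import STRAND_INDEX, CoverageExperiment

__all__ = [
    "TSSOrientation",
    "TSSRecord",
    "TSSConfig",
    "AntisenseCall",
    "detect_tss",
    "detect_tss_both_strands",
    "orient_tss",
    "call_antisense_genes",
    "tss_profile",
    "group_tss_profile",
    "tss_to_bed",
]


class TSSOrientation(enum.Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"
    INTERNAL_SENSE = "internal_sense"
    ORPHAN = "orphan"


@dataclass(frozen=True)
class TSSRecord:
    """A detected transcription start: 0-based first transcribed base."""

    position: int
    strand: Strand
    step_ratio: float  # downstream/upstream mean depth; may be inf over silence
    orientation: TSSOrientation | None = None
    target_feature: str | None = None


@dataclass(frozen=True)
class TSSConfig:
    window: int = 20  # nt, each side of the candidate position
    step_ratio_min: float = 5.0
    min_coverage: float = 10.0  # required mean depth downstream of the step
    replicate_quorum: int | None = None  # None -> all replicates
    upstream_max: int = 250  # nt, max promoter-to-gene-start distance for "sense"
    antisense_downstream_max: int = 100  # nt past a gene's 3' end still counted antisense


@dataclass(frozen=True)
class AntisenseCall:
    feature_id: str
    n_timepoints_antisense_dominant: int
    called: bool


def _window_means(cov: np.ndarray, w: int, strand: Strand) -> tuple[np.ndarray, np.ndarray, int]:
    """Upstream/downstream window means for every valid candidate position.

    ``cov`` has genome position on the last axis.  Downstream means the
    transcribed side: positions [p, p+w) on the forward strand and
    [p-w+1, p+1) on the reverse strand.  Returns (up, down, first_pos) where
    the arrays cover candidate positions first_pos .. first_pos+n-1.
    """
    L = cov.shape[-1]
    cs = np.concatenate(
        [np.zeros(cov.shape[:-1] + (1,)), np.cumsum(cov, axis=-1)], axis=-1
    )
    if strand is Strand.FORWARD:
        # candidates p in [w, L-w]
        p0 = w
        p_hi = L - w
        idx = np.arange(p0, p_hi + 1)
        up = (cs[..., idx] - cs[..., idx - w]) / w
        down = (cs[..., idx + w] - cs[..., idx]) / w
    else:
        # candidates p in [w-1, L-w-1]
        p0 = w - 1
        p_hi = L - w - 1
        idx = np.arange(p0, p_hi + 1)
        down = (cs[..., idx + 1] - cs[..., idx + 1 - w]) / w
        up = (cs[..., idx + 1 + w] - cs[..., idx + 1]) / w
    return up, down, p0


def _ratio(down: np.ndarray, up: np.ndarray) -> np.ndarray:
    """down/up with the convention 0/0 -> 0 and x/0 -> inf for x > 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(up > 0, down / np.where(up > 0, up, 1.0), np.where(down > 0, np.inf, 0.0))
    return r


def detect_tss(
    exp: CoverageExperiment, strand: Strand, cfg: TSSConfig = TSSConfig()
) -> list[TSSRecord]:
    """Detect TSS positions on one strand as reproducible coverage up-steps.

    Candidate runs of qualifying positions are collapsed to a single site:
    the position maximising the pooled step ratio, ties broken by maximal
    downstream depth, remaining ties to the leftmost base on the forward
    strand and the rightmost on the reverse strand (so a clean step is
    reported at its exact first transcribed base).
    """
    w = cfg.window
    if w <= 0:
        raise ValueError("window must be positive")
    if w >= exp.genome_length:
        raise ValueError(f"window {w} >= genome length {exp.genome_length}")
    quorum = cfg.replicate_quorum if cfg.replicate_quorum is not None else exp.n_replicates
    cov = exp.strand_tracks(strand)  # (T, R, L)

    up_rep, down_rep, p0 = _window_means(cov, w, strand)  # (T, R, P)
    pooled = cov.mean(axis=1)  # replicate-mean depth (T, L)
    up_pool, down_pool, _ = _window_means(pooled, w, strand)  # (T, P)

    # timepoint of maximal local expression, per candidate position
    tp_star = np.argmax(down_pool, axis=0)  # (P,)
    P = tp_star.size
    cols = np.arange(P)
    ratio_rep = _ratio(down_rep, up_rep)
    pass_rep = (ratio_rep >= cfg.step_ratio_min) & (down_rep >= cfg.min_coverage)
    n_pass = pass_rep[tp_star, :, cols].sum(axis=1)  # replicates passing at tp*

    ratio_pool = _ratio(down_pool, up_pool)[tp_star, cols]
    down_at = down_pool[tp_star, cols]
    qualify = (
        (n_pass >= quorum)
        & (ratio_pool >= cfg.step_ratio_min)
        & (down_at >= cfg.min_coverage)
    )

    records: list[TSSRecord] = []
    q = np.flatnonzero(qualify)
    if q.size == 0:
        return records
    # split qualifying candidates into runs of consecutive positions
    breaks = np.flatnonzero(np.diff(q) > 1) + 1
    for run in np.split(q, breaks):
        r = ratio_pool[run]
        best = run[r == r.max()]
        d = down_at[best]
        best = best[d == d.max()]
        pick = best[0] if strand is Strand.FORWARD else best[-1]
        records.append(
            TSSRecord(position=int(pick + p0), strand=strand, step_ratio=float(ratio_pool[pick]))
        )
    return records


def detect_tss_both_strands(
    exp: CoverageExperiment, cfg: TSSConfig = TSSConfig()
) -> list[TSSRecord]:
    recs = detect_tss(exp, Strand.FORWARD, cfg) + detect_tss(exp, Strand.REVERSE, cfg)
    return sorted(recs, key=lambda t: (t.position, t.strand.value))


def _upstream_distance(pos: int, feat: AnnotatedFeature) -> int:
    """Distance from a same-strand TSS to the feature's 5' start (>=0 if upstream)."""
    return feat.start - pos if feat.strand is Strand.FORWARD else pos - (feat.end - 1)


def orient_tss(
    tss: TSSRecord,
    ann: GenomeAnnotation,
    cfg: TSSConfig = TSSConfig(),
    *,
    precedence: tuple[TSSOrientation, ...] = (
        TSSOrientation.INTERNAL_SENSE,
        TSSOrientation.SENSE,
        TSSOrientation.ANTISENSE,
    ),
) -> TSSRecord:
    """Classify a TSS against the annotation and attach its target feature.

    sense: within ``upstream_max`` nt upstream of a same-strand gene start
    and not inside any same-strand gene; internal_sense: inside a
    same-strand gene downstream of its start (internal promoter); antisense:
    inside, or within ``antisense_downstream_max`` nt past the 3' end of, an
    opposite-strand gene.  When several apply the first match in
    ``precedence`` wins; orphan otherwise.
    """
    pos = tss.position
    candidates: dict[TSSOrientation, str] = {}

    same = [f for f in ann.features if f.strand is tss.strand]
    inside_same = [f for f in same if f.start <= pos < f.end]
    internal = [f for f in inside_same if pos != f.five_prime]
    if internal:
        candidates[TSSOrientation.INTERNAL_SENSE] = internal[0].feature_id
    if not inside_same:
        ahead = [f for f in same if 0 <= _upstream_distance(pos, f) <= cfg.upstream_max]
        if ahead:
            nearest = min(ahead, key=lambda f: _upstream_distance(pos, f))
            candidates[TSSOrientation.SENSE] = nearest.feature_id
    opp = [f for f in ann.features if f.strand is not tss.strand]
    anti = []
    for f in opp:
        if f.start <= pos < f.end:
            anti.append((0, f))
        else:
            # past the feature's 3' end, on the side an asRNA would start from
            d = f.start - pos if f.strand is Strand.REVERSE else pos - (f.end - 1)
            if 0 < d <= cfg.antisense_downstream_max:
                anti.append((d, f))
    if anti:
        candidates[TSSOrientation.ANTISENSE] = min(anti, key=lambda x: x[0])[1].feature_id

    for orient in precedence:
        if orient in candidates:
            return replace(tss, orientation=orient, target_feature=candidates[orient])
    return replace(tss, orientation=TSSOrientation.ORPHAN, target_feature=None)


def call_antisense_genes(
    exp: CoverageExperiment,
    ann: GenomeAnnotation,
    *,
    antisense_min_timepoints: int = 3,
) -> list[AntisenseCall]:
    """Call genes with more antisense than sense reads at enough timepoints.

    For each feature and timepoint the replicate-summed depth over the
    feature interval is compared between the antisense and sense strands;
    timepoints with a strict antisense excess are counted and a gene is
    called when that count reaches ``antisense_min_timepoints``.
    """
    calls = []
    for f in ann.features:
        si = STRAND_INDEX[f.strand]
        sense = exp.tracks[:, :, si, f.start : f.end].sum(axis=(1, 2))
        anti = exp.tracks[:, :, 1 - si, f.start : f.end].sum(axis=(1, 2))
        n = int(np.sum(anti > sense))
        calls.append(AntisenseCall(f.feature_id, n, n >= antisense_min_timepoints))
    return calls


def tss_profile(
    exp: CoverageExperiment, tss: TSSRecord, *, window: int = 20
) -> np.ndarray:
    """Percent-of-max coverage over timepoints in the window just downstream of a TSS."""
    if tss.strand is Strand.FORWARD:
        lo, hi = tss.position, tss.position + window
    else:
        lo, hi = tss.position - window + 1, tss.position + 1
    if lo < 0 or hi > exp.genome_length:
        warnings.warn(
            f"TSS window [{lo},{hi}) truncated to genome bounds", stacklevel=2
        )
        lo, hi = max(lo, 0), min(hi, exp.genome_length)
    si = STRAND_INDEX[tss.strand]
    per_tp = exp.tracks[:, :, si, lo:hi].mean(axis=(1, 2))
    peak = per_tp.max()
    return 100.0 * per_tp / peak if peak > 0 else np.full_like(per_tp, np.nan)


def group_tss_profile(profiles: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard deviation (per timepoint) over a group of TSS profiles."""
    stack = np.vstack(profiles)
    return stack.mean(axis=0), stack.std(axis=0)


def tss_to_bed(records: list[TSSRecord], chrom: str) -> pd.DataFrame:
    """BED6 table of TSSs; score is the step ratio rounded and capped at 1000."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [t.position for t in records],
            "end": [t.position + 1 for t in records],
            "name": [t.orientation.value if t.orientation else "tss" for t in records],
            "score": [
                1000 if not np.isfinite(t.step_ratio) else int(min(round(t.step_ratio), 1000))
                for t in records
            ],
            "strand": [t.strand.value for t in records],
        }
    )
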