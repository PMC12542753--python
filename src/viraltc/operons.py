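"""Transcriptional-unit (operon) assembly from gene neighbourhood, temporal
class, coverage continuity, and detected TSSs.

Same-strand neighbouring genes are chained greedily in transcription order;
two consecutive genes stay in one unit iff

(i)   their intergenic gap is at most ``gap_max`` nt (overlaps allowed),
(ii)  they share the same temporal class,
(iii) coverage is continuous across the joined span at its peak timepoint,

and no promoter intervenes: a sense TSS in the intergenic interval, or an
internal promoter inside the downstream gene, starts a new unit at that TSS
(the downstream gene then belongs to the new unit with its 5' end truncated
relative to that transcript).  Every unit is expected to start at a
detected TSS; units without one are kept but flagged as orphans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotatedFeature, GenomeAnnotation, Strand
from .classify import TemporalClass
from .coverage import CoverageExperiment
from .tss import TSSConfig, TSSOrientation, TSSRecord, orient_tss

__all__ = ["Operon", "OperonConfig", "assemble", "summarize", "operons_to_table"]


@dataclass(frozen=True)
class OperonConfig:
    gap_max: int = 30  # nt; negative gaps (overlapping stop/start codons) always pass
    continuity_frac: float = 0.9  # fraction of spanned bases that must be covered
    continuity_min_cov: float = 5.0  # depth counting as "covered"


@dataclass
class Operon:
    operon_id: str
    members: list[str]  # feature_ids in transcription order
    strand: Strand
    leading_tss: TSSRecord | None
    class_label: TemporalClass
    flags: list[str] = field(default_factory=list)

    @property
    def monocistronic(self) -> bool:
        return len(self.members) == 1


def _gap(u: AnnotatedFeature, v: AnnotatedFeature) -> int:
    """Signed intergenic gap between transcription-order neighbours u -> v."""
    return v.start - u.end if u.strand is Strand.FORWARD else u.start - v.end


def _intergenic_interval(u: AnnotatedFeature, v: AnnotatedFeature) -> tuple[int, int]:
    return (u.end, v.start) if u.strand is Strand.FORWARD else (v.end, u.start)


def _is_internal_tss_in(tss: TSSRecord, feat: AnnotatedFeature) -> bool:
    return (
        tss.strand is feat.strand
        and feat.start <= tss.position < feat.end
        and tss.position != feat.five_prime
    )


def _continuity_ok(
    exp: CoverageExperiment, strand: Strand, lo: int, hi: int, cfg: OperonConfig
) -> bool:
    """Criterion (iii) over [lo, hi) at the span's peak timepoint."""
    pooled = exp.strand_tracks(strand).mean(axis=1)[:, lo:hi]  # replicate-mean (T, span)
    tp = int(np.argmax(pooled.sum(axis=1)))
    return float(np.mean(pooled[tp] >= cfg.continuity_min_cov)) >= cfg.continuity_frac


def joinable(
    u: AnnotatedFeature,
    v: AnnotatedFeature,
    classes: dict[str, TemporalClass],
    exp: CoverageExperiment,
    tsss: list[TSSRecord],
    cfg: OperonConfig = OperonConfig(),
) -> bool:
    """Whether transcription-order neighbours u -> v belong to one unit."""
    if u.strand is not v.strand:
        raise ValueError("joinable() requires same-strand features")
    if _gap(u, v) > cfg.gap_max:
        return False
    if classes[u.feature_id] is not classes[v.feature_id]:
        return False
    glo, ghi = _intergenic_interval(u, v)
    internal_in_u: TSSRecord | None = None
    for t in tsss:
        if t.strand is not u.strand:
            continue
        if t.orientation is TSSOrientation.SENSE and glo <= t.position < ghi:
            return False  # promoter in the intergenic gap starts a new unit
        if t.orientation is TSSOrientation.INTERNAL_SENSE:
            if _is_internal_tss_in(t, v):
                return False  # internal promoter: v heads a new (5'-truncated) unit
            if _is_internal_tss_in(t, u):
                internal_in_u = t
    # continuity is judged over the transcribed part of the pair: when u is
    # transcribed from an internal promoter its untranscribed 5' prefix does
    # not count against coverage continuity
    lo = min(u.start, v.start)
    hi = max(u.end, v.end)
    if internal_in_u is not None:
        if u.strand is Strand.FORWARD:
            lo = max(lo, internal_in_u.position)
        else:
            hi = min(hi, internal_in_u.position + 1)
    return _continuity_ok(exp, u.strand, lo, hi, cfg)


def _upstream_distance_to(pos: int, feat: AnnotatedFeature) -> int:
    return feat.start - pos if feat.strand is Strand.FORWARD else pos - (feat.end - 1)


def _leading_tss(
    first: AnnotatedFeature, tsss: list[TSSRecord], tss_cfg: TSSConfig
) -> tuple[TSSRecord | None, list[str]]:
    sense = [
        t
        for t in tsss
        if t.strand is first.strand
        and t.orientation is TSSOrientation.SENSE
        and (
            t.target_feature == first.feature_id
            or (
                t.target_feature is None
                and 0 <= _upstream_distance_to(t.position, first) <= tss_cfg.upstream_max
            )
        )
    ]
    if sense:
        if first.strand is Strand.FORWARD:
            best = max(sense, key=lambda t: t.position)  # nearest upstream
        else:
            best = min(sense, key=lambda t: t.position)
        return best, []
    internal = [
        t
        for t in tsss
        if t.orientation is TSSOrientation.INTERNAL_SENSE and _is_internal_tss_in(t, first)
    ]
    if internal:
        # unit initiated inside its first gene: transcript misses that gene's 5' end
        if first.strand is Strand.FORWARD:
            best = min(internal, key=lambda t: t.position)
        else:
            best = max(internal, key=lambda t: t.position)
        return best, ["truncated_first_member"]
    return None, ["no_tss"]


def assemble(
    ann: GenomeAnnotation,
    classes: dict[str, TemporalClass],
    exp: CoverageExperiment,
    tsss: list[TSSRecord],
    cfg: OperonConfig = OperonConfig(),
    tss_cfg: TSSConfig = TSSConfig(),
) -> list[Operon]:
    """Partition all classified features into transcriptional units.

    ``classes`` must cover every feature of the annotation; features labelled
    unclassified (unexpressed) are excluded from the partition.  TSS records
    lacking an orientation are oriented against the annotation first.
    """
    missing = [f.feature_id for f in ann.features if f.feature_id not in classes]
    if missing:
        raise ValueError(f"class map missing features: {missing}")
    tsss = [
        t if t.orientation is not None else orient_tss(t, ann, tss_cfg) for t in tsss
    ]

    units: list[Operon] = []
    for strand in (Strand.FORWARD, Strand.REVERSE):
        feats = [
            f
            for f in ann.on_strand(strand)
            if classes[f.feature_id] is not TemporalClass.UNCLASSIFIED
        ]
        if strand is Strand.REVERSE:
            feats = feats[::-1]  # transcription order: right to left
        chain: list[AnnotatedFeature] = []
        for f in feats:
            if chain and joinable(chain[-1], f, classes, exp, tsss, cfg):
                chain.append(f)
            else:
                if chain:
                    units.append(_close(chain, classes, tsss, tss_cfg))
                chain = [f]
        if chain:
            units.append(_close(chain, classes, tsss, tss_cfg))

    # order units by genomic position of their first member
    pos = {f.feature_id: f.start for f in ann.features}
    units.sort(key=lambda u: min(pos[m] for m in u.members))
    for i, u in enumerate(units, start=1):
        u.operon_id = f"TU{i:03d}"
    return units


def _close(
    chain: list[AnnotatedFeature],
    classes: dict[str, TemporalClass],
    tsss: list[TSSRecord],
    tss_cfg: TSSConfig,
) -> Operon:
    first = chain[0]
    lead, flags = _leading_tss(first, tsss, tss_cfg)
    return Operon(
        operon_id="",
        members=[f.feature_id for f in chain],
        strand=first.strand,
        leading_tss=lead,
        class_label=classes[first.feature_id],
        flags=flags,
    )


def summarize(operons: list[Operon]) -> dict:
    """Unit-count arithmetic: size, monocistronic fraction, mean genes/unit."""
    if not operons:
        raise ValueError("no operons to summarize")
    n_units = len(operons)
    n_mono = sum(1 for o in operons if o.monocistronic)
    n_genes = sum(len(o.members) for o in operons)
    return {
        "n_units": n_units,
        "n_genes": n_genes,
        "n_monocistronic": n_mono,
        "pct_monocistronic": round(100.0 * n_mono / n_units, 1),
        "mean_genes_per_operon": n_genes / n_units,
    }


def operons_to_table(operons: list[Operon]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "operon_id": [o.operon_id for o in operons],
            "members": [",".join(o.members) for o in operons],
            "n_members": [len(o.members) for o in operons],
            "strand": [o.strand.value for o in operons],
            "tss_pos1": [o.leading_tss.position + 1 if o.leading_tss else None for o in operons],
            "class": [o.class_label.value for o in operons],
            "monocistronic": [o.monocistronic for o in operons],
            "flags": [";".join(o.flags) for o in operons],
        }
    )
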