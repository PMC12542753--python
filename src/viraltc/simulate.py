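"""Synthetic infection time-course experiments with planted ground truth.

The generator emulates a stranded RNA-seq time course over a small lytic
viral genome: transcriptional units of same-strand genes are laid out with
operon-like spacing (occasional 4-nt stop/start overlaps, short intragenic
gaps, longer inter-unit gaps), each unit carries a temporal archetype
profile (early / middle / middle-down / late percent-of-max shapes), and
per-base coverage is the unit amplitude scaled by the profile and the
sample's library size, with optional Poisson or negative-binomial noise.
TSSs are realised as coverage steps at transcript 5' ends; one (or more)
unit is split by an internal promoter inside a gene body; antisense
transcripts with a late-type profile are planted on the opposite strand of
structural/replication genes.  A matched host gene universe with category
labels and planted differentially expressed genes is generated alongside.

Every quantity downstream code estimates (temporal class, TSS position,
unit partition, antisense dominance, host DEG sets) is recorded as ground
truth, self-consistent with the noise-free signal by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    AnnotatedFeature,
    FeatureKind,
    GenomeAnnotation,
    Strand,
    read_annotation,
    write_annotation,
)
from .classify import TemporalClass
from .coverage import (
    DEFAULT_TIMEPOINTS,
    STRAND_INDEX,
    CoverageExperiment,
    read_bedgraph_set,
    write_bedgraph,
)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "SimulatedBundle",
    "ARCHETYPES",
    "ANTISENSE_ARCHETYPE",
    "simulate",
    "write_fixture",
    "read_fixture",
]

#: Percent-of-max archetypes over the default 5/20/60/120/180/300 min grid.
#: Shapes satisfy the half-maximum classification rule by construction:
#: early reaches 50% by 20 min, middle/middle-down first at 60 min
#: (middle-down later decaying below 50%), late first at 180 min.
ARCHETYPES: dict[TemporalClass, tuple[float, ...]] = {
    TemporalClass.EARLY: (100.0, 85.0, 45.0, 30.0, 20.0, 12.0),
    TemporalClass.MIDDLE: (8.0, 30.0, 100.0, 92.0, 85.0, 80.0),
    TemporalClass.MIDDLE_DOWN: (8.0, 35.0, 100.0, 42.0, 25.0, 15.0),
    TemporalClass.LATE: (2.0, 6.0, 15.0, 40.0, 100.0, 88.0),
}

#: Antisense transcripts follow a late-type shape peaking at 180 min.
ANTISENSE_ARCHETYPE: tuple[float, ...] = (2.0, 5.0, 12.0, 45.0, 100.0, 70.0)

_REFERENCE_LIBRARY = 1_000_000.0

#: Functional modules assignable to planted units; antisense transcripts are
#: planted over the first two (structural and replication-associated genes).
_FUNCTION_LABELS = ("structural", "DNA metabolism", "transcription", "lysis", "unknown")
_FUNCTION_PROBS = (0.30, 0.20, 0.10, 0.10, 0.30)
_ANTISENSE_HOST_FUNCTIONS = ("structural", "DNA metabolism")


def _default_class_mix() -> dict[str, float]:
    return {"early": 0.07, "middle": 0.25, "middle_down": 0.14, "late": 0.54}


def _default_host_planted_deg() -> dict[int, tuple[int, int]]:
    # (up, down) per timepoint; totals mirror a sparse-early / rich-late course
    return {5: (0, 0), 20: (4, 3), 60: (70, 65), 120: (129, 118), 180: (234, 200), 300: (204, 170)}


@dataclass
class SimulationSpec:
    seed: int = 0
    genome_length: int = 36_000
    n_features: int = 80  # ORFs; tRNAs come on top
    n_trna: int = 1
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    n_internal_promoters: int = 1
    n_antisense_tss: int = 23
    noise: str = "poisson"  # none | poisson | nb
    nb_dispersion: float = 0.05
    mean_depth: float = 50.0
    p_forward: float = 0.7
    # host universe
    host_n_genes: int = 4053
    host_n_categories: int = 20
    host_planted_deg: dict[int, tuple[int, int]] = field(default_factory=_default_host_planted_deg)
    host_planted_lfc: float = 2.0  # log2 units
    host_nb_dispersion: float = 0.05
    # planted worked-example category: 37-gene category holding 5 of the
    # down-regulated genes at 120 min
    enrich_category: str = "N"
    enrich_category_size: int = 37
    enrich_planted_in_category: int = 5
    enrich_timepoint: int = 120

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {total}")
        if self.noise not in ("none", "poisson", "nb"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class GroundTruth:
    classes: dict[str, str]  # feature_id -> temporal class value
    operons: list[dict]  # members (transcription order), strand, tss_position, class, truncated
    tss: list[dict]  # position, strand, kind (sense | internal_sense | antisense)
    antisense_dominant: list[str]
    antisense_counts: dict[str, int]
    host_degs: dict[int, dict[str, list[str]]]  # timepoint -> {"up": [...], "down": [...]}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["host_degs"] = {str(t): v for t, v in self.host_degs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["host_degs"] = {int(t): v for t, v in d["host_degs"].items()}
        return cls(**d)


@dataclass
class SimulatedBundle:
    spec: SimulationSpec
    annotation: GenomeAnnotation
    experiment: CoverageExperiment
    host_counts: dict[int, dict[str, pd.DataFrame]]  # tp -> {"infected": df, "control": df}
    category_map: pd.Series
    truth: GroundTruth


# ---------------------------------------------------------------------------
# viral genome and coverage


def _draw_unit_sizes(rng: np.random.Generator, n_features: int) -> list[int]:
    sizes: list[int] = []
    choices = np.array([1, 2, 3, 4, 5, 6, 7])
    probs = np.array([0.42, 0.14, 0.14, 0.12, 0.08, 0.05, 0.05])
    while sum(sizes) < n_features:
        sizes.append(int(rng.choice(choices, p=probs)))
    sizes[-1] -= sum(sizes) - n_features
    if sizes[-1] == 0:
        sizes.pop()
    return sizes


def _draw_class(rng: np.random.Generator, mix: dict[str, float]) -> TemporalClass:
    labels = sorted(mix)
    probs = np.array([mix[l] for l in labels])
    return TemporalClass(rng.choice(labels, p=probs / probs.sum()))


def simulate(spec: SimulationSpec) -> SimulatedBundle:
    """Generate a full synthetic experiment with planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    T = len(spec.timepoints)
    R = spec.n_replicates
    L = spec.genome_length

    # --- transcriptional-unit skeleton -------------------------------------
    sizes = _draw_unit_sizes(rng, spec.n_features)
    internal_idx: set[int] = set()
    if spec.n_internal_promoters > 0:
        big = [i for i, s in enumerate(sizes) if s >= 4]
        while len(big) < spec.n_internal_promoters and sizes:
            j = int(np.argmax(sizes))
            sizes[j] = max(sizes[j], 4)
            big = [i for i, s in enumerate(sizes) if s >= 4]
        internal_idx = set(rng.choice(big, size=min(spec.n_internal_promoters, len(big)), replace=False).tolist())

    # blocks: contiguous gene runs; an internal-promoter block holds two units
    blocks: list[dict] = []
    for i, s in enumerate(sizes):
        strand = Strand.FORWARD if rng.random() < spec.p_forward else Strand.REVERSE
        function = str(rng.choice(_FUNCTION_LABELS, p=_FUNCTION_PROBS))
        if i in internal_idx:
            k = s // 2
            unit_sizes = [k, s - k]
            unit_classes = [_draw_class(rng, spec.class_mix), _draw_class(rng, spec.class_mix)]
            # the internal-promoter unit is the transcriptionally downstream
            # one: the right unit on the forward strand, the left on reverse
            internal = [False, True] if strand is Strand.FORWARD else [True, False]
        else:
            unit_sizes = [s]
            unit_classes = [_draw_class(rng, spec.class_mix)]
            internal = [False]
        blocks.append(
            {
                "strand": strand,
                "function": function,
                "unit_sizes": unit_sizes,
                "unit_classes": unit_classes,
                "internal": internal,
                "is_trna": False,
            }
        )
    for _ in range(spec.n_trna):
        blocks.append(
            {
                "strand": Strand.FORWARD if rng.random() < spec.p_forward else Strand.REVERSE,
                "function": "tRNA",
                "unit_sizes": [1],
                "unit_classes": [_draw_class(rng, spec.class_mix)],
                "internal": [False],
                "is_trna": True,
            }
        )
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    # --- genome layout (two passes: draw, then shrink inter-unit gaps if the
    # draw would overflow the genome; gaps never go below 50 nt) -------------
    lead = int(rng.integers(120, 200))
    tail = 120
    for b in blocks:
        n_genes = sum(b["unit_sizes"])
        b["gene_lengths"] = [
            78 if b["is_trna"] else 3 * int(rng.integers(50, 151)) for _ in range(n_genes)
        ]
        b["intra_gaps"] = [
            -4 if rng.random() < 0.3 else int(rng.integers(0, 21)) for _ in range(n_genes - 1)
        ]
    inter_gaps = [int(rng.integers(80, 400)) for _ in blocks]
    block_span = [sum(b["gene_lengths"]) + sum(b["intra_gaps"]) for b in blocks]
    overshoot = lead + sum(block_span) + sum(inter_gaps) + tail - L
    if overshoot > 0:
        budget = L - lead - sum(block_span) - tail
        scale = budget / sum(inter_gaps)
        inter_gaps = [max(50, int(g * scale)) for g in inter_gaps]
    if lead + sum(block_span) + sum(inter_gaps) + tail > L:
        need = lead + sum(block_span) + 50 * len(blocks) + tail
        raise ValueError(
            f"planted features need {need} nt but genome_length is {L}; "
            "increase genome_length or reduce n_features"
        )

    pos = lead
    feat_tuples: list[tuple[int, int, Strand, FeatureKind, str]] = []
    for b, gap_after in zip(blocks, inter_gaps):
        b["gene_slots"] = []
        for j, length in enumerate(b["gene_lengths"]):
            if j > 0:
                pos += b["intra_gaps"][j - 1]
            b["gene_slots"].append((pos, pos + length))
            feat_tuples.append(
                (
                    pos,
                    pos + length,
                    b["strand"],
                    FeatureKind.TRNA if b["is_trna"] else FeatureKind.ORF,
                    b["function"],
                )
            )
            pos += length
        pos += gap_after

    # name features in genome order
    feat_tuples_sorted = sorted(range(len(feat_tuples)), key=lambda i: feat_tuples[i][0])
    names = {}
    n_orf = 0
    n_t = 0
    for rank, i in enumerate(feat_tuples_sorted):
        if feat_tuples[i][3] is FeatureKind.TRNA:
            n_t += 1
            names[i] = f"trna{n_t}"
        else:
            n_orf += 1
            names[i] = f"gp{n_orf:02d}"
    features = [
        AnnotatedFeature(names[i], s, e, strand, kind, fg)
        for i, (s, e, strand, kind, fg) in enumerate(feat_tuples)
    ]
    ann = GenomeAnnotation("synthgenome", L, features, "linear")

    # map block gene slots back to feature ids (layout order == feat_tuples order)
    fid_iter = iter(range(len(feat_tuples)))
    for b in blocks:
        b["gene_ids"] = [names[next(fid_iter)] for _ in b["gene_slots"]]

    # --- units, TSSs, amplitudes -------------------------------------------
    lib = np.rint(_REFERENCE_LIBRARY * rng.uniform(0.85, 1.15, size=(T, R))).astype(float)
    lam = np.zeros((T, R, 2, L))
    feat_by_id = {f.feature_id: f for f in ann.features}

    truth_classes: dict[str, str] = {}
    truth_operons: list[dict] = []
    truth_tss: list[dict] = []

    def _add_transcript(span_lo: int, span_hi: int, strand: Strand, pct: tuple[float, ...], amp: float) -> None:
        si = STRAND_INDEX[strand]
        base = amp * np.asarray(pct) / 100.0  # (T,)
        scale = lib / _REFERENCE_LIBRARY  # (T, R)
        lam[:, :, si, span_lo:span_hi] += (base[:, None] * scale)[:, :, None]

    for b in blocks:
        gidx = 0
        for u, (usize, uclass, uinternal) in enumerate(
            zip(b["unit_sizes"], b["unit_classes"], b["internal"])
        ):
            ids = b["gene_ids"][gidx : gidx + usize]
            slots = b["gene_slots"][gidx : gidx + usize]
            gidx += usize
            lo = min(s for s, _ in slots)
            hi = max(e for _, e in slots)
            amp = spec.mean_depth * rng.uniform(0.6, 1.6)
            if b["strand"] is Strand.FORWARD:
                members = ids
                first = feat_by_id[members[0]]
                if uinternal:
                    off = int(rng.integers(max(3, first.length // 4), max(4, first.length // 2)))
                    tss = first.start + off
                else:
                    tss = first.start - int(rng.integers(20, 61))
                span = (tss, hi)
            else:
                members = ids[::-1]  # transcription order: right to left
                first = feat_by_id[members[0]]
                if uinternal:
                    off = int(rng.integers(max(3, first.length // 4), max(4, first.length // 2)))
                    tss = first.end - 1 - off
                else:
                    tss = first.end - 1 + int(rng.integers(20, 41))
                span = (lo, tss + 1)
            _add_transcript(span[0], span[1], b["strand"], ARCHETYPES[uclass], amp)
            for fid in members:
                truth_classes[fid] = uclass.value
            truth_tss.append(
                {
                    "position": int(tss),
                    "strand": b["strand"].value,
                    "kind": "internal_sense" if uinternal else "sense",
                }
            )
            truth_operons.append(
                {
                    "members": list(members),
                    "strand": b["strand"].value,
                    "tss_position": int(tss),
                    "class": uclass.value,
                    "truncated": bool(uinternal),
                }
            )

    # --- antisense transcripts ---------------------------------------------
    eligible = [
        f
        for f in ann.features
        if f.functional_group in _ANTISENSE_HOST_FUNCTIONS and f.kind is FeatureKind.ORF
    ]
    eligible.sort(key=lambda f: f.start)
    picked = rng.permutation(len(eligible))[: spec.n_antisense_tss]
    chosen = [eligible[int(i)] for i in picked]
    if len(chosen) < spec.n_antisense_tss:
        warnings.warn(
            f"placed {len(chosen)} antisense TSSs (requested {spec.n_antisense_tss})",
            stacklevel=2,
        )
    # the asRNA stays inside its host gene, with a margin on the far edge so
    # that the planted step of a neighbouring gene's asRNA cannot fall inside
    # this TSS's detection window
    far_margin = 26
    for g in sorted(chosen, key=lambda f: f.start):
        amp = spec.mean_depth * rng.uniform(0.4, 1.4)
        wobble = max(1, g.length // 8)
        if g.strand is Strand.FORWARD:  # asRNA on the reverse strand
            tss = g.end - 1 - int(rng.integers(0, wobble))
            span = (g.start + far_margin + int(rng.integers(0, wobble)), tss + 1)
            as_strand = Strand.REVERSE
        else:
            tss = g.start + int(rng.integers(0, wobble))
            span = (tss, g.end - far_margin - int(rng.integers(0, wobble)))
            as_strand = Strand.FORWARD
        _add_transcript(span[0], span[1], as_strand, ANTISENSE_ARCHETYPE, amp)
        truth_tss.append({"position": int(tss), "strand": as_strand.value, "kind": "antisense"})

    # --- antisense dominance truth from the noise-free expected signal -----
    anti_counts: dict[str, int] = {}
    for f in ann.features:
        si = STRAND_INDEX[f.strand]
        sense = lam[:, :, si, f.start : f.end].sum(axis=(1, 2))
        anti = lam[:, :, 1 - si, f.start : f.end].sum(axis=(1, 2))
        anti_counts[f.feature_id] = int(np.sum(anti > sense))
    anti_set = sorted(fid for fid, n in anti_counts.items() if n >= 3)

    # --- noise --------------------------------------------------------------
    if spec.noise == "none":
        tracks = lam.copy()
    elif spec.noise == "poisson":
        tracks = rng.poisson(lam).astype(float)
    else:  # nb: gamma-poisson mixture per base
        phi = spec.nb_dispersion
        shape = 1.0 / phi
        mix = np.where(lam > 0, rng.gamma(shape, 1.0, size=lam.shape) * phi * lam, 0.0)
        tracks = rng.poisson(mix).astype(float)
    exp = CoverageExperiment(L, spec.timepoints, R, tracks, lib)

    # --- host universe ------------------------------------------------------
    category_map, host_counts, host_truth = _simulate_host(spec, rng)

    truth = GroundTruth(
        classes=truth_classes,
        operons=truth_operons,
        tss=sorted(truth_tss, key=lambda t: (t["position"], t["strand"])),
        antisense_dominant=anti_set,
        antisense_counts=anti_counts,
        host_degs=host_truth,
    )
    return SimulatedBundle(spec, ann, exp, host_counts, category_map, truth)


# ---------------------------------------------------------------------------
# host counts


def _simulate_host(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[pd.Series, dict[int, dict[str, pd.DataFrame]], dict[int, dict[str, list[str]]]]:
    G = spec.host_n_genes
    genes = [f"H{i + 1:04d}" for i in range(G)]

    # category letters: the worked-example category, unknown (S), and fillers
    letters = [spec.enrich_category, "S"]
    fillers = [c for c in "JKLBDVTMUOCGEFHIPQRWXYZ" if c not in letters]
    letters += fillers[: max(0, spec.host_n_categories - 2)]
    n_special = spec.enrich_category_size
    n_unknown = int(round(0.427 * G))  # unknown-function fraction of the universe
    remaining = G - n_special - n_unknown
    n_fill = len(letters) - 2
    base = remaining // n_fill
    sizes = [n_special, n_unknown] + [base] * n_fill
    sizes[-1] += remaining - base * n_fill
    labels = np.repeat(letters, sizes)
    rng.shuffle(labels)
    category_map = pd.Series(labels, index=genes, name="category")

    mu = np.exp(rng.normal(np.log(80.0), 1.0, size=G))
    mu = np.clip(mu, 1.0, 5000.0)
    expressed = np.flatnonzero(mu >= 10)
    mu_by_gene = dict(zip(genes, mu))

    special_genes = [g for g in genes if category_map[g] == spec.enrich_category]
    special_expressed = [g for g in special_genes if mu_by_gene[g] >= 10]

    # planted DEG sets: shared cores plus per-timepoint extras; the
    # worked-example category contributes only to the down sets
    tps = sorted(spec.host_planted_deg)
    non_special = [genes[i] for i in expressed if category_map[genes[i]] != spec.enrich_category]
    pool = list(rng.permutation(non_special))
    n_core_special = spec.enrich_planted_in_category
    special_pick = list(rng.choice(special_expressed, size=n_core_special, replace=False))
    pool = [g for g in pool if g not in special_pick]
    pool_up, pool_down = pool[: len(pool) // 2], pool[len(pool) // 2 :]

    host_truth: dict[int, dict[str, list[str]]] = {}
    for t in tps:
        n_up, n_down = spec.host_planted_deg[t]
        up = pool_up[:n_up]
        down: list[str] = []
        if n_down > 0 and t >= spec.enrich_timepoint:
            down += special_pick
        down += pool_down[: n_down - len(down)]
        host_truth[t] = {"up": sorted(up), "down": sorted(down)}

    host_counts: dict[int, dict[str, pd.DataFrame]] = {}
    R = spec.n_replicates
    phi = spec.host_nb_dispersion
    for t in tps:
        lfc = np.zeros(G)
        up = set(host_truth[t]["up"])
        down = set(host_truth[t]["down"])
        for i, g in enumerate(genes):
            if g in up:
                lfc[i] = spec.host_planted_lfc
            elif g in down:
                lfc[i] = -spec.host_planted_lfc
        mats = {}
        for cond in ("infected", "control"):
            mean = mu * (2.0 ** lfc) if cond == "infected" else mu
            cols = {}
            for r in range(R):
                m = mean * rng.uniform(0.9, 1.1)  # per-sample depth factor
                if spec.noise == "none":
                    counts = np.rint(m)
                else:
                    counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * m))
                cols[f"rep{r + 1}"] = counts.astype(int)
            mats[cond] = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
        host_counts[t] = mats
    return category_map, host_counts, host_truth


# ---------------------------------------------------------------------------
# on-disk fixtures


def write_fixture(bundle: SimulatedBundle, outdir: str | Path) -> None:
    """Write a simulated experiment as plain-text files readable by the package.

    Layout: annotation.gff3, coverage/*.bedgraph + manifest.tsv,
    host/{infected,control}_t*.tsv + category_map.tsv, ground_truth.json.
    """
    outdir = Path(outdir)
    (outdir / "coverage").mkdir(parents=True, exist_ok=True)
    (outdir / "host").mkdir(exist_ok=True)
    write_annotation(bundle.annotation, outdir / "annotation.gff3")

    exp = bundle.experiment
    rows = []
    for ti, t in enumerate(exp.timepoints):
        for r in range(exp.n_replicates):
            for strand, tag in ((Strand.FORWARD, "fwd"), (Strand.REVERSE, "rev")):
                rel = f"coverage/t{t}_rep{r + 1}_{tag}.bedgraph"
                write_bedgraph(
                    exp.tracks[ti, r, STRAND_INDEX[strand]],
                    outdir / rel,
                    bundle.annotation.genome_id,
                )
                rows.append(
                    {
                        "path": rel,
                        "timepoint_min": t,
                        "replicate": r + 1,
                        "strand": strand.value,
                        "library_size": int(exp.library_size[ti, r]),
                    }
                )
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)

    for t, mats in bundle.host_counts.items():
        for cond, df in mats.items():
            df.to_csv(outdir / "host" / f"{cond}_t{t}.tsv", sep="\t")
    bundle.category_map.rename_axis("gene").to_csv(outdir / "host" / "category_map.tsv", sep="\t")

    meta = {
        "genome_length": bundle.annotation.genome_length,
        "timepoints": list(exp.timepoints),
        "n_replicates": exp.n_replicates,
        "seed": bundle.spec.seed,
        "noise": bundle.spec.noise,
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps({"meta": meta, "truth": bundle.truth.to_dict()}, indent=1)
    )


def read_fixture(fixture_dir: str | Path):
    """Read back a fixture directory written by :func:`write_fixture`.

    Returns (annotation, experiment, host_counts, category_map, truth).
    """
    fixture_dir = Path(fixture_dir)
    payload = json.loads((fixture_dir / "ground_truth.json").read_text())
    meta = payload["meta"]
    truth = GroundTruth.from_dict(payload["truth"])
    ann = read_annotation(fixture_dir / "annotation.gff3")
    ann.genome_length = meta["genome_length"]
    exp = read_bedgraph_set(fixture_dir / "manifest.tsv", meta["genome_length"])
    host_counts: dict[int, dict[str, pd.DataFrame]] = {}
    for t in meta["timepoints"]:
        inf_p = fixture_dir / "host" / f"infected_t{t}.tsv"
        if not inf_p.exists():
            continue
        host_counts[t] = {
            "infected": pd.read_csv(inf_p, sep="\t", index_col=0),
            "control": pd.read_csv(fixture_dir / "host" / f"control_t{t}.tsv", sep="\t", index_col=0),
        }
    cat = pd.read_csv(fixture_dir / "host" / "category_map.tsv", sep="\t", index_col=0)["category"]
    return ann, exp, host_counts, cat, truth
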