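"""Stranded per-base coverage over an infection time course, and RPKM profiles.

The raw signal is a 4-dimensional array of per-base read depth indexed by
(timepoint, replicate, strand, genome position), together with per-sample
library sizes (total mapped reads, host plus virus).  Expression of a gene
g at timepoint t is summarised as

    RPKM_g(t) = count_equiv × 1e9 / (length_nt × library_size)

where ``count_equiv`` converts the per-base depth sum over the gene to an
approximate read count by dividing by a nominal read length.  Temporal
shape is carried by the percent-of-max profile

    pct_g(t) = 100 · RPKM_g(t) / max_t RPKM_g(t)

computed on replicate-averaged RPKM; the read-length constant and any
uniform rescaling of depth or library size cancel in pct_g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotatedFeature, Strand

__all__ = [
    "CoverageExperiment",
    "TemporalProfile",
    "CoverageError",
    "read_bedgraph_set",
    "write_bedgraph",
    "gene_rpkm",
    "temporal_profile",
    "DEFAULT_TIMEPOINTS",
]

DEFAULT_TIMEPOINTS: tuple[int, ...] = (5, 20, 60, 120, 180, 300)

#: strand axis order in the coverage array
STRAND_INDEX = {Strand.FORWARD: 0, Strand.REVERSE: 1}


class CoverageError(ValueError):
    """Raised for malformed coverage input."""


@dataclass
class CoverageExperiment:
    """Per-base stranded coverage for every (timepoint, replicate) sample.

    ``tracks`` has shape (n_timepoints, n_replicates, 2, genome_length) with
    strand axis ordered (forward, reverse); ``library_size`` has shape
    (n_timepoints, n_replicates).
    """

    genome_length: int
    timepoints: tuple[int, ...]
    n_replicates: int
    tracks: np.ndarray
    library_size: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = tuple(self.timepoints)
        self.tracks = np.asarray(self.tracks, dtype=float)
        self.library_size = np.asarray(self.library_size, dtype=float)
        expected = (len(self.timepoints), self.n_replicates, 2, self.genome_length)
        if self.tracks.shape != expected:
            raise CoverageError(f"tracks shape {self.tracks.shape} != expected {expected}")
        if self.library_size.shape != expected[:2]:
            raise CoverageError(
                f"library_size shape {self.library_size.shape} != expected {expected[:2]}"
            )
        if np.any(self.tracks < 0):
            raise CoverageError("negative coverage values")
        if np.any(self.library_size <= 0):
            raise CoverageError("library sizes must be positive")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise CoverageError(f"timepoints not strictly increasing: {self.timepoints}")

    def track(self, timepoint: int, replicate: int, strand: Strand) -> np.ndarray:
        """Per-base depth array for one sample and strand."""
        return self.tracks[self.timepoints.index(timepoint), replicate, STRAND_INDEX[strand]]

    def strand_tracks(self, strand: Strand) -> np.ndarray:
        """(n_timepoints, n_replicates, genome_length) view of one strand."""
        return self.tracks[:, :, STRAND_INDEX[strand], :]


@dataclass
class TemporalProfile:
    """Replicate-averaged RPKM and percent-of-max vectors for one feature."""

    feature_id: str
    timepoints: tuple[int, ...]
    rpkm: np.ndarray
    pct_of_max: np.ndarray
    expressed: bool

    def __post_init__(self) -> None:
        self.rpkm = np.asarray(self.rpkm, dtype=float)
        self.pct_of_max = np.asarray(self.pct_of_max, dtype=float)


def write_bedgraph(depth: np.ndarray, path: str | Path, chrom: str) -> None:
    """Write a per-base depth array as run-length-encoded bedGraph (0-based half-open)."""
    depth = np.asarray(depth)
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [depth.size]))
    values = depth[starts]
    keep = values != 0  # uncovered runs are implicit
    df = pd.DataFrame(
        {"chrom": chrom, "start": starts[keep], "end": ends[keep], "value": values[keep]}
    )
    # %.17g keeps depth values bit-exact across a write/read round trip
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.17g")


def _read_bedgraph(path: Path, genome_length: int) -> np.ndarray:
    depth = np.zeros(genome_length, dtype=float)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        return depth
    if len(df) == 0:
        return depth
    df = df.sort_values("start", kind="stable")
    starts = df["start"].to_numpy(int)
    ends = df["end"].to_numpy(int)
    if np.any(ends[:-1] > starts[1:]):
        i = int(np.flatnonzero(ends[:-1] > starts[1:])[0])
        raise CoverageError(
            f"{path.name}: overlapping intervals "
            f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
        )
    if starts[0] < 0 or ends[-1] > genome_length:
        raise CoverageError(f"{path.name}: interval outside genome of length {genome_length}")
    values = df["value"].to_numpy(float)
    # bedGraph is 0-based half-open: interval (s, e, v) sets depth[s:e] = v
    for s, e, v in zip(starts, ends, values):
        depth[s:e] = v
    return depth


def read_bedgraph_set(manifest_path: str | Path, genome_length: int) -> CoverageExperiment:
    """Assemble a :class:`CoverageExperiment` from a manifest of bedGraph files.

    The manifest is a TSV with columns ``path, timepoint_min, replicate,
    strand, library_size``; one row per (timepoint, replicate, strand).
    Relative paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CoverageError(f"manifest not found: {manifest_path}")
    man = pd.read_csv(manifest_path, sep="\t")
    required = {"path", "timepoint_min", "replicate", "strand", "library_size"}
    if not required.issubset(man.columns):
        raise CoverageError(f"manifest missing columns {sorted(required - set(man.columns))}")
    timepoints = tuple(sorted(man["timepoint_min"].unique()))
    replicates = sorted(man["replicate"].unique())
    n_rep = len(replicates)
    rep_index = {r: i for i, r in enumerate(replicates)}
    have = {(r.timepoint_min, r.replicate, r.strand) for r in man.itertuples()}
    missing = [
        (t, r, s)
        for t in timepoints
        for r in replicates
        for s in ("+", "-")
        if (t, r, s) not in have
    ]
    if missing:
        raise CoverageError(f"manifest missing (timepoint, replicate, strand) combinations: {missing}")

    tracks = np.zeros((len(timepoints), n_rep, 2, genome_length))
    library_size = np.zeros((len(timepoints), n_rep))
    for row in man.itertuples():
        ti = timepoints.index(row.timepoint_min)
        ri = rep_index[row.replicate]
        si = STRAND_INDEX[Strand.from_symbol(str(row.strand))]
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        tracks[ti, ri, si] = _read_bedgraph(p, genome_length)
        library_size[ti, ri] = row.library_size
    return CoverageExperiment(genome_length, timepoints, n_rep, tracks, library_size)


def gene_rpkm(
    exp: CoverageExperiment,
    feat: AnnotatedFeature,
    timepoint: int,
    replicate: int,
    *,
    read_length_proxy: float = 75.0,
) -> float:
    """RPKM of ``feat`` in one sample, from sense-strand depth over the feature.

    The per-base depth sum over [start, end) is divided by
    ``read_length_proxy`` (nominal read length, nt) to approximate a read
    count, then scaled by 1e9 / (length × library_size).  Percent-of-max
    profiles are invariant to the proxy constant.
    """
    if feat.length <= 0:
        raise CoverageError(f"zero-length feature {feat.feature_id!r}")
    if feat.end > exp.genome_length:
        raise CoverageError(f"feature {feat.feature_id!r} outside genome")
    depth = exp.track(timepoint, replicate, feat.strand)[feat.start : feat.end]
    count_equiv = float(depth.sum()) / read_length_proxy
    lib = exp.library_size[exp.timepoints.index(timepoint), replicate]
    return count_equiv * 1e9 / (feat.length * lib)


def temporal_profile(
    exp: CoverageExperiment,
    feat: AnnotatedFeature,
    *,
    read_length_proxy: float = 75.0,
    expression_floor: float = 1.0,
) -> TemporalProfile:
    """Replicate-averaged RPKM and percent-of-max profile of one feature.

    RPKM is averaged over replicates per timepoint *before* the
    percent-of-max transform.  Features whose maximal replicate-averaged
    RPKM falls below ``expression_floor`` are flagged unexpressed and get a
    NaN percent profile rather than a shape fitted to noise.
    """
    rpkm = np.array(
        [
            np.mean(
                [
                    gene_rpkm(exp, feat, t, r, read_length_proxy=read_length_proxy)
                    for r in range(exp.n_replicates)
                ]
            )
            for t in exp.timepoints
        ]
    )
    peak = rpkm.max()
    expressed = bool(peak >= expression_floor)
    if peak > 0:
        pct = 100.0 * rpkm / peak
    else:
        pct = np.full_like(rpkm, np.nan)
    return TemporalProfile(feat.feature_id, exp.timepoints, rpkm, pct, expressed)


def profiles_to_table(profiles: list[TemporalProfile]) -> pd.DataFrame:
    """Long-format TSV-ready table of RPKM and percent-of-max profiles."""
    rows = []
    for p in profiles:
        for i, t in enumerate(p.timepoints):
            rows.append(
                {
                    "feature_id": p.feature_id,
                    "timepoint_min": t,
                    "rpkm": p.rpkm[i],
                    "pct_of_max": p.pct_of_max[i],
                    "expressed": p.expressed,
                }
            )
    return pd.DataFrame(rows)
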