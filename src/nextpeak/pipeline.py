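"""The five-step peak-calling pipeline and the motif-based evaluation metrics.

Steps: (1) read mapped tags, (2) select candidate regions by windowed counts,
(3) train or accept the global shape (sigma, beta), (4) fit every region and
run both tests, (5) screen, rank by estimated binding intensity 2*nu_hat, and
recommend screening cut-offs when motif sites are available.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_regions as ior
from .inference import DEFAULT_SHAPE, RegionFit, fit_global, fit_region
from .io_regions import MappabilityTrack, Region, TagTracks
from .model import GlobalShape

logger = logging.getLogger(__name__)

__all__ = [
    "PeakCall",
    "EvalSummary",
    "call_peaks",
    "rank_peaks",
    "screen_peaks",
    "recommend_cutoffs",
    "evaluate_against_motifs",
    "estimate_fragment_length",
    "write_peaks",
    "read_peaks",
]

#: screening-recommendation search grid: region-length and GOF p-value cutoffs
CUTOFF_LENGTH_GRID = (200, 300, 400, 500)
CUTOFF_PVALUE_GRID = (1e-2, 1e-4, 1e-6, 1e-8)


@dataclass
class PeakCall:
    """One reportable peak: region, estimated site, rank statistic, tests."""

    chrom: str
    start: int
    end: int
    site: float  # mu_hat
    se_mu: float
    binding_intensity: float  # 2 * nu_hat, the rank statistic
    lr_stat: float
    lr_pvalue: float
    gof_stat: float
    gof_df: int
    gof_pvalue: float
    nu_hat: float
    rho_hat: float
    converged: bool
    screened: bool = False
    rank: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class EvalSummary:
    """Motif-based evaluation: TP = peak within ``radius`` bp of a site;
    bias is signed, negative when the peak lies upstream of the site."""

    n_true_positive: int
    mean_distance: float
    mean_bias: float
    precision_curve: np.ndarray


def estimate_fragment_length(beta: float, tag_length: float) -> float:
    """Average sonication fragment length implied by the fitted model.

    Both fragment ends sit an average of beta bp from the cross-link, and a
    right tag's reported location is the leftmost base of the tag, hence
    2*beta + d - 1 for tag length d.
    """
    return 2.0 * beta + tag_length - 1.0


def _peak_from_fit(region: Region, fit: RegionFit) -> PeakCall:
    p = fit.params_hat
    return PeakCall(
        chrom=region.chrom,
        start=region.start,
        end=region.end,
        site=p.mu,
        se_mu=fit.se_mu,
        binding_intensity=2.0 * p.nu,
        lr_stat=fit.lr_stat,
        lr_pvalue=fit.lr_pvalue,
        gof_stat=fit.gof_stat,
        gof_df=fit.gof_df,
        gof_pvalue=fit.gof_pvalue,
        nu_hat=p.nu,
        rho_hat=p.rho,
        converged=fit.converged,
    )


def rank_peaks(peaks: list[PeakCall]) -> list[PeakCall]:
    """Rank unscreened peaks by descending binding intensity 2*nu_hat.

    Ties break by smaller LR p-value, then by coordinate.  Non-converged fits
    sort after converged ones; screened peaks keep no rank and are appended in
    coordinate order.  Input order is irrelevant.
    """
    ranked = [dataclasses.replace(p) for p in peaks if not p.screened]
    ranked.sort(
        key=lambda p: (
            not p.converged,
            -p.binding_intensity,
            p.lr_pvalue,
            p.chrom,
            p.start,
        )
    )
    for i, p in enumerate(ranked, start=1):
        p.rank = i
    rest = [dataclasses.replace(p, rank=None) for p in peaks if p.screened]
    rest.sort(key=lambda p: (p.chrom, p.start))
    return ranked + rest


def screen_peaks(
    peaks: list[PeakCall], max_length: int, min_gof_pvalue: float
) -> list[PeakCall]:
    """Flag (mask) peaks whose region is shorter than ``max_length`` AND whose
    goodness-of-fit p-value falls below ``min_gof_pvalue`` — short ill-fitting
    regions are PCR-spike suspects.  Long ill-fitting regions stay: they are
    multiple-binding candidates set aside for further analysis.  Peaks with an
    undefined GOF test (df <= 0, NaN p) are kept.  Fit values are untouched;
    the survivors are re-ranked.
    """
    flagged = []
    for p in peaks:
        masked = (
            p.length < max_length
            and not math.isnan(p.gof_pvalue)
            and p.gof_pvalue < min_gof_pvalue
        )
        flagged.append(dataclasses.replace(p, screened=masked))
    return rank_peaks(flagged)


def _sites_by_chrom(motif_sites) -> dict[str, np.ndarray]:
    by: dict[str, list[float]] = {}
    for chrom, pos in motif_sites:
        by.setdefault(chrom, []).append(float(pos))
    return {c: np.sort(np.asarray(v)) for c, v in by.items()}


def _nearest_site(sites: np.ndarray, x: float) -> float:
    i = int(np.searchsorted(sites, x))
    cands = sites[max(i - 1, 0) : i + 1]
    return float(cands[np.argmin(np.abs(cands - x))])


def evaluate_against_motifs(
    peaks: list[PeakCall], motif_sites, radius: float = 250.0
) -> EvalSummary:
    """Score ranked peaks against candidate motif sites.

    A peak is a true positive iff its nearest same-chromosome site lies within
    ``radius`` bp.  ``mean_distance`` averages |peak - site| over TPs;
    ``mean_bias`` averages the signed offset (peak - site), negative when the
    peak sits upstream of the site.  ``precision_curve[r-1]`` is the TP
    fraction among the top r ranked peaks.
    """
    by_chrom = _sites_by_chrom(motif_sites)
    ranked = sorted(
        (p for p in peaks if not p.screened and p.rank is not None),
        key=lambda p: p.rank,
    )
    is_tp = np.zeros(len(ranked), dtype=bool)
    offsets = []
    for i, p in enumerate(ranked):
        sites = by_chrom.get(p.chrom)
        if sites is None or sites.size == 0:
            continue
        site = _nearest_site(sites, p.site)
        if abs(p.site - site) <= radius:
            is_tp[i] = True
            offsets.append(p.site - site)
    offsets = np.asarray(offsets)
    n_tp = int(is_tp.sum())
    precision = (
        np.cumsum(is_tp) / np.arange(1, len(ranked) + 1)
        if ranked
        else np.empty(0)
    )
    return EvalSummary(
        n_true_positive=n_tp,
        mean_distance=float(np.mean(np.abs(offsets))) if n_tp else float("nan"),
        mean_bias=float(np.mean(offsets)) if n_tp else float("nan"),
        precision_curve=precision,
    )


def _precision_auc(peaks, motif_sites, radius, max_rank=10_000) -> float:
    summary = evaluate_against_motifs(peaks, motif_sites, radius=radius)
    curve = summary.precision_curve[: min(max_rank, summary.precision_curve.size)]
    return float(curve.sum())


def recommend_cutoffs(
    peaks: list[PeakCall],
    motif_sites,
    radius: float = 250.0,
    length_grid=CUTOFF_LENGTH_GRID,
    pvalue_grid=CUTOFF_PVALUE_GRID,
    max_rank: int = 10_000,
) -> tuple[int, float]:
    """Recommend (length_cutoff, pvalue_cutoff) for the GOF screen by grid
    search, maximizing the area under the precision-vs-rank curve truncated at
    rank min(``max_rank``, N).  Ties resolve to the least aggressive pair
    (smallest length, then smallest p-value threshold)."""
    if motif_sites is None or len(list(motif_sites)) == 0:
        raise ValueError("cut-off recommendation requires motif sites")
    motif_sites = list(motif_sites)
    best_pair, best_auc = None, -np.inf
    for length in sorted(length_grid):
        for pvalue in sorted(pvalue_grid):
            screened = screen_peaks(peaks, length, pvalue)
            auc = _precision_auc(screened, motif_sites, radius, max_rank)
            if auc > best_auc + 1e-12:
                best_auc = auc
                best_pair = (int(length), float(pvalue))
    return best_pair


def call_peaks(
    tags_path=None,
    *,
    records=None,
    tag_format: str = "bed",
    mappability_path=None,
    mappability: MappabilityTrack | None = None,
    shape: GlobalShape | None = None,
    motif_sites=None,
    window: int = 150,
    min_count: int = 15,
    screen_length: int | None = None,
    screen_pvalue: float | None = None,
    train_max_regions: int = 100,
) -> list[PeakCall]:
    """Run the full pipeline and return ranked peak calls.

    Input is either a tag file (``tags_path`` + ``tag_format``) or an iterable
    of TagRecords.  If ``shape`` is None and motif sites are given, (sigma,
    beta) are trained on the strongest motif-anchored regions; otherwise the
    defaults (sigma=30, beta=50) apply.  If both screening cutoffs are set the
    GOF screen is applied before ranking.  Deterministic given inputs.
    """
    if records is None:
        if tags_path is None:
            raise ValueError("either tags_path or records is required")
        records = ior.read_mapped_tags(tags_path, format=tag_format)
    if mappability is None and mappability_path is not None:
        mappability = ior.read_mappability(mappability_path)
    records = ior.filter_unmappable_tags(records, mappability)
    tracks = TagTracks.from_records(records)
    logger.info("ingested %d tags on %d chromosome(s)", tracks.n_tags, len(tracks.chroms))

    regions = ior.select_regions(tracks, window=window, min_count=min_count)
    if not regions:
        logger.warning("no candidate regions selected (window=%d, min_count=%d)", window, min_count)
        return []
    logger.info("selected %d candidate regions", len(regions))

    region_tags = [ior.extract_region_tags(r, tracks, mappability) for r in regions]

    if shape is None:
        shape = _train_shape(regions, region_tags, motif_sites, train_max_regions)

    peaks = []
    n_fail = 0
    for region, tags in zip(regions, region_tags):
        fit = fit_region(tags, shape)
        n_fail += not fit.converged
        peaks.append(_peak_from_fit(region, fit))
    if n_fail:
        logger.warning("%d region fit(s) did not fully converge", n_fail)

    if screen_length is not None and screen_pvalue is not None:
        peaks = screen_peaks(peaks, screen_length, screen_pvalue)
        logger.info("screened %d peak(s)", sum(p.screened for p in peaks))
    else:
        peaks = rank_peaks(peaks)
    return peaks


def _train_shape(regions, region_tags, motif_sites, train_max_regions) -> GlobalShape:
    if not motif_sites:
        logger.info("no motif sites: using default shape sigma=%.0f beta=%.0f",
                    DEFAULT_SHAPE.sigma, DEFAULT_SHAPE.beta)
        return DEFAULT_SHAPE
    by_chrom = _sites_by_chrom(motif_sites)
    candidates = []
    for region, tags in zip(regions, region_tags):
        sites = by_chrom.get(region.chrom)
        if sites is None:
            continue
        inside = sites[(sites >= region.start) & (sites <= region.end)]
        if inside.size == 0:
            continue
        center = 0.5 * (region.start + region.end)
        anchor = float(inside[np.argmin(np.abs(inside - center))])
        candidates.append((region.total_count, tags, anchor))
    if not candidates:
        logger.info("no motif-anchored regions: using default shape")
        return DEFAULT_SHAPE
    candidates.sort(key=lambda t: -t[0])
    candidates = candidates[:train_max_regions]
    shape = fit_global([c[1] for c in candidates], [c[2] for c in candidates])
    logger.info("trained shape on %d regions: sigma=%.2f beta=%.2f",
                len(candidates), shape.sigma, shape.beta)
    return shape


_TSV_COLUMNS = [
    "chrom", "start", "end", "site", "se_mu", "binding_intensity",
    "lr_stat", "lr_pvalue", "gof_stat", "gof_df", "gof_pvalue",
    "nu_hat", "rho_hat", "converged", "screened", "rank",
]


def write_peaks(peaks: list[PeakCall], out_prefix) -> dict[str, Path]:
    """Write ``<prefix>.bed`` (BED6, 0-based half-open single-base site
    intervals, score = 2*nu_hat) and ``<prefix>.tsv`` with every fit field.
    Empty peak lists yield a headered TSV and an empty BED."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"bed": prefix.with_suffix(".bed"), "tsv": prefix.with_suffix(".tsv")}
    with open(paths["bed"], "w") as fh:
        for i, p in enumerate(peaks):
            site = int(round(p.site))
            name = f"peak{p.rank}" if p.rank is not None else f"screened{i}"
            fh.write(
                f"{p.chrom}\t{site - 1}\t{site}\t{name}\t{p.binding_intensity:.4f}\t.\n"
            )
    df = pd.DataFrame(
        [{c: getattr(p, c) for c in _TSV_COLUMNS} for p in peaks],
        columns=_TSV_COLUMNS,
    )
    df.to_csv(paths["tsv"], sep="\t", index=False, float_format="%.6g")
    return paths


def read_peaks(tsv_path) -> list[PeakCall]:
    """Round-trip reader for the TSV written by :func:`write_peaks`."""
    df = pd.read_csv(tsv_path, sep="\t")
    peaks = []
    for row in df.itertuples(index=False):
        rank = row.rank
        peaks.append(
            PeakCall(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                site=float(row.site),
                se_mu=float(row.se_mu),
                binding_intensity=float(row.binding_intensity),
                lr_stat=float(row.lr_stat),
                lr_pvalue=float(row.lr_pvalue),
                gof_stat=float(row.gof_stat),
                gof_df=int(row.gof_df),
                gof_pvalue=float(row.gof_pvalue),
                nu_hat=float(row.nu_hat),
                rho_hat=float(row.rho_hat),
                converged=bool(row.converged),
                screened=bool(row.screened),
                rank=None if pd.isna(rank) else int(rank),
            )
        )
    return peaks
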