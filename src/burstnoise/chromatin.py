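"""Per-gene histone-mark intensity scoring, TSS metaprofiles, and promoter
nucleosome occupancy.

A gene's range is the strand-relative interval from 2 kb upstream of its TSS
to its TES. The intensity of a mark on a gene is the peak-length-weighted
mean signal over that range,

    score = sum_i L_i * E_i / L        (L_i, E_i: clipped peak length, signal)

with L the full gene range length ("gene_length" variant) or the length of
the union of the clipped peaks ("peak_covered_length" variant, the default).
Genes with no overlapping peak score 0 under the gene-length variant and are
flagged no-peak under the union variant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GeneAnnotation, MidpointTrack, PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "gene_range",
    "mark_intensity",
    "metaprofile",
    "nucleosome_occupancy",
    "OCCUPANCY_REGIONS",
]

OCCUPANCY_REGIONS = (250, 200, 150, 100)


def gene_range(annotation: GeneAnnotation, upstream: int = 2000) -> pd.DataFrame:
    """Strand-relative [TSS - upstream, TES) interval per gene, clipped at 0.

    Returns columns chrom, start, end, length.
    """
    t = annotation.table
    plus = (t["strand"] == "+").to_numpy()
    tss = t["tss"].to_numpy()
    tes = t["tes"].to_numpy()
    start = np.where(plus, tss - upstream, tes)
    end = np.where(plus, tes, tss + upstream)
    clipped = start < 0
    if clipped.any():
        logger.info("clipping %d gene ranges at position 0", int(clipped.sum()))
        start = np.maximum(start, 0)
    out = pd.DataFrame(
        {"chrom": t["chrom"].to_numpy(), "start": start, "end": end,
         "length": end - start},
        index=t.index,
    )
    return out


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def mark_intensity(
    peaks: dict[str, PeakSet] | PeakSet,
    annotation: GeneAnnotation,
    variant: str = "peak_covered_length",
    upstream: int = 2000,
) -> pd.DataFrame:
    """Score every gene for every mark; returns a gene x mark table.

    For each mark a boolean companion column ``<mark>_no_peak`` flags genes
    with no overlapping peak (score 0 in both variants).
    """
    if variant not in {"gene_length", "peak_covered_length"}:
        raise ValueError(f"unknown scoring variant {variant!r}")
    if isinstance(peaks, PeakSet):
        peaks = {"mark": peaks}
    ranges = gene_range(annotation, upstream)
    out = pd.DataFrame(index=annotation.gene_ids)
    for mark, peakset in peaks.items():
        scores = np.zeros(len(ranges))
        no_peak = np.zeros(len(ranges), dtype=bool)
        for i, row in enumerate(ranges.itertuples(index=False)):
            hits = peakset.overlapping(row.chrom, row.start, row.end)
            if not hits:
                no_peak[i] = True
                continue
            clipped = [(max(s, row.start), min(e, row.end), sig) for s, e, sig in hits]
            weighted = sum((e - s) * sig for s, e, sig in clipped)
            if variant == "gene_length":
                denom = row.length
            else:
                denom = _merged_length([(s, e) for s, e, _ in clipped])
            scores[i] = weighted / denom
        out[mark] = scores
        out[f"{mark}_no_peak"] = no_peak
    return out


def metaprofile(
    peaks: dict[str, PeakSet] | PeakSet,
    annotation: GeneAnnotation,
    window: tuple[int, int] = (-2000, 4000),
    bin_width: int = 100,
    promoter_boundary: int = 500,
    promoter_mass_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean signal around the TSS in strand-relative offset bins.

    Returns ``(profile, localization)``: the profile has one row per bin
    (indexed by bin start offset) and one column per mark, each entry the
    mean over genes of the mean signal in that bin (0 where uncovered);
    ``localization`` calls each mark "promoter" when more than
    ``promoter_mass_threshold`` of the profile mass lies at offsets below
    ``promoter_boundary``, else "gene_body".
    """
    lo, hi = window
    if (hi - lo) % bin_width:
        raise ValueError("bins must tile the window exactly")
    if isinstance(peaks, PeakSet):
        peaks = {"mark": peaks}
    edges = np.arange(lo, hi + bin_width, bin_width)
    n_bins = len(edges) - 1
    t = annotation.table
    plus = (t["strand"] == "+").to_numpy()
    tss = t["tss"].to_numpy()
    chroms = t["chrom"].to_numpy()

    profile = pd.DataFrame(index=pd.Index(edges[:-1], name="offset_bin"))
    localization = {}
    for mark, peakset in peaks.items():
        acc = np.zeros(n_bins)
        for g in range(len(t)):
            # genomic window corresponding to strand-relative offsets [lo, hi)
            if plus[g]:
                w_start, w_end = tss[g] + lo, tss[g] + hi
            else:
                w_start, w_end = tss[g] - hi, tss[g] - lo
            sig = np.zeros(n_bins)
            for s, e, value in peakset.overlapping(chroms[g], max(w_start, 0), w_end):
                s, e = max(s, w_start), min(e, w_end)
                if plus[g]:
                    off_s, off_e = s - tss[g], e - tss[g]
                else:
                    off_s, off_e = tss[g] - e, tss[g] - s
                # distribute overlap across bins, weighting by covered bases
                first = int((off_s - lo) // bin_width)
                last = int((off_e - 1 - lo) // bin_width)
                for k in range(max(first, 0), min(last, n_bins - 1) + 1):
                    ov = min(off_e, edges[k + 1]) - max(off_s, edges[k])
                    sig[k] += value * ov / bin_width
            acc += sig
        mean_sig = acc / len(t)
        profile[mark] = mean_sig
        total = mean_sig.sum()
        if total <= 0:
            localization[mark] = "gene_body"
            continue
        upstream_mass = mean_sig[edges[:-1] + bin_width <= promoter_boundary].sum()
        localization[mark] = (
            "promoter" if upstream_mass / total > promoter_mass_threshold else "gene_body"
        )
    return profile, pd.Series(localization, name="localization")


def nucleosome_occupancy(track: MidpointTrack, region_length: int = 250) -> pd.Series:
    """Sum of midpoint counts at offsets 1..region_length upstream of the TSS."""
    if region_length < 1:
        raise ValueError("region_length must be >= 1")
    values = {}
    for gid, x in track.counts.items():
        if len(x) < region_length:
            raise ValueError(
                f"midpoint track for {gid} covers {len(x)} bp < region {region_length}"
            )
        values[gid] = int(x[:region_length].sum())
    return pd.Series(values, name=f"occupancy_{region_length}")
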