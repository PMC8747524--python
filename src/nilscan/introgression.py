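"""Donor-introgression scanning and common-introgressed-region detection.

At informative loci — sites where the donor and recurrent parents are
opposite homozygotes — a NIL's allele reveals its local ancestry.
Each chromosome is scanned in non-overlapping windows (default 1 Mb);
a window is donor-flagged when it holds enough donor-homozygous calls,
both in count and as a fraction of the classified informative calls it
contains.  Runs of flagged windows (bridging a configurable gap) are
merged and refined inward to the outermost donor-allele locus, giving
SNP-resolution introgressed segments.  Intersecting segments across
two or more NILs yields common introgressed regions (CIRs) along with
the set of informative loci at which every NIL is donor-homozygous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nilscan.genotypes import CallClass, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InformativeLocus:
    """A parent-divergent site with its donor and recurrent alleles."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vtype: str
    donor_allele: str
    recurrent_allele: str

    @property
    def donor_is_alt(self) -> bool:
        return self.donor_allele == self.alt


@dataclass(frozen=True)
class IntrogressionSegment:
    """A donor-derived interval in one NIL (0-based half-open)."""

    nil: str
    chrom: str
    start: int
    end: int
    n_donor_loci: int
    n_informative_loci: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.n_donor_loci > self.n_informative_loci:
            raise ValueError("donor loci cannot exceed informative loci")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class CommonIntrogressedRegion:
    """Interval introgressed in every NIL under comparison."""

    chrom: str
    start: int
    end: int
    per_nil_counts: dict[str, int]
    common_snps: list[InformativeLocus]

    @property
    def n_common(self) -> int:
        return len(self.common_snps)


def find_informative_loci(
    matrix: GenotypeMatrix,
    donor: str,
    recurrent: str,
    vtypes: Sequence[str] = ("SNP", "InDel"),
) -> tuple[list[InformativeLocus], dict[str, int]]:
    """Loci where donor and recurrent are opposite homozygotes.

    Returns the loci plus a tally of the discarded categories
    (het, unclassified, concordant).
    """
    if donor == recurrent:
        raise ValueError("donor and recurrent samples must differ")
    for s in (donor, recurrent):
        if s not in matrix.samples:
            raise KeyError(f"sample {s!r} not in matrix (has {matrix.samples})")
    tallies = {"informative": 0, "het": 0, "unclassified": 0, "concordant": 0}
    loci: list[InformativeLocus] = []
    dcol = matrix.calls[donor].to_numpy()
    rcol = matrix.calls[recurrent].to_numpy()
    sites = matrix.sites
    for i in range(len(matrix)):
        if sites.iloc[i]["vtype"] not in vtypes:
            continue
        d, r = dcol[i], rcol[i]
        if "e" in (d, r):
            tallies["het"] += 1
        elif "u" in (d, r):
            tallies["unclassified"] += 1
        elif d == r:
            tallies["concordant"] += 1
        else:  # opposite homozygotes
            tallies["informative"] += 1
            row = sites.iloc[i]
            donor_allele = row["alt"] if d == "h" else row["ref"]
            rec_allele = row["ref"] if d == "h" else row["alt"]
            loci.append(
                InformativeLocus(
                    chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"],
                    alt=row["alt"], vtype=row["vtype"],
                    donor_allele=donor_allele, recurrent_allele=rec_allele,
                )
            )
    return loci, tallies


def nil_donor_calls(
    matrix: GenotypeMatrix, loci: Sequence[InformativeLocus], nil: str
) -> pd.DataFrame:
    """Per-locus NIL status at informative loci.

    Columns: chrom, pos, donor (donor-homozygous), het, classified.
    Heterozygous calls count as classified non-donor; unclassified
    calls are excluded from window denominators.
    """
    if nil not in matrix.samples:
        raise KeyError(f"sample {nil!r} not in matrix")
    key = matrix.sites.set_index(["chrom", "pos", "ref", "alt"]).index
    call_by_site = dict(zip(key, matrix.calls[nil]))
    rows = []
    for loc in loci:
        call = call_by_site.get((loc.chrom, loc.pos, loc.ref, loc.alt), "u")
        donor_code = "h" if loc.donor_is_alt else "l"
        rows.append(
            (
                loc.chrom,
                loc.pos,
                call == donor_code,
                call == "e",
                call in ("h", "l", "e"),
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "donor", "het", "classified"])


def scan_windows(
    calls: pd.DataFrame,
    window_size: int = 1_000_000,
    min_donor_loci: int = 5,
    min_donor_frac: float = 0.8,
) -> pd.DataFrame:
    """Flag fixed windows containing donor-derived alleles.

    ``calls`` is the output of :func:`nil_donor_calls`.  Windows are
    [k*w, (k+1)*w); a window is flagged when it holds at least
    ``min_donor_loci`` donor-homozygous calls and those calls make up
    at least ``min_donor_frac`` of its classified informative calls.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    out = []
    for chrom, grp in calls.groupby("chrom", sort=False):
        win = ((grp["pos"] - 1) // window_size).to_numpy()
        for k in np.unique(win):
            sel = grp[win == k]
            n_class = int(sel["classified"].sum())
            n_donor = int(sel["donor"].sum())
            frac = n_donor / n_class if n_class else 0.0
            flagged = n_donor >= min_donor_loci and frac >= min_donor_frac
            out.append(
                (chrom, int(k) * window_size, (int(k) + 1) * window_size,
                 len(sel), n_class, n_donor, frac, flagged)
            )
    return pd.DataFrame(
        out,
        columns=["chrom", "start", "end", "n_loci", "n_classified",
                 "n_donor", "donor_frac", "flagged"],
    )


def merge_segments(
    windows: pd.DataFrame,
    calls: pd.DataFrame,
    nil: str = "NIL",
    max_gap_windows: int = 1,
) -> list[IntrogressionSegment]:
    """Merge runs of flagged windows and refine to donor-locus bounds.

    Flagged windows separated by at most ``max_gap_windows`` unflagged
    windows are joined; segment boundaries are then pulled inward to
    the first and last donor-allele locus, so reported coordinates are
    at SNP resolution rather than window resolution.
    """
    segments: list[IntrogressionSegment] = []
    if windows.empty:
        return segments
    window_size = int((windows["end"] - windows["start"]).iloc[0])
    for chrom, grp in windows.groupby("chrom", sort=False):
        flagged = grp[grp["flagged"]].sort_values("start")
        if flagged.empty:
            continue
        runs: list[tuple[int, int]] = []
        for _, row in flagged.iterrows():
            s, e = int(row["start"]), int(row["end"])
            if runs and s - runs[-1][1] <= max_gap_windows * window_size:
                runs[-1] = (runs[-1][0], e)
            else:
                runs.append((s, e))
        chrom_calls = calls[calls["chrom"] == chrom]
        for s, e in runs:
            inside = chrom_calls[
                (chrom_calls["pos"] > s) & (chrom_calls["pos"] <= e)
            ]
            donor_pos = inside.loc[inside["donor"], "pos"]
            if donor_pos.empty:
                continue
            start = int(donor_pos.min()) - 1  # 0-based half-open
            end = int(donor_pos.max())
            n_inf = int(
                inside[(inside["pos"] > start) & (inside["pos"] <= end)][
                    "classified"
                ].sum()
            )
            segments.append(
                IntrogressionSegment(
                    nil=nil, chrom=chrom, start=start, end=end,
                    n_donor_loci=int(donor_pos.size),
                    n_informative_loci=n_inf,
                )
            )
    return segments


def find_segments(
    matrix: GenotypeMatrix,
    loci: Sequence[InformativeLocus],
    nil: str,
    window_size: int = 1_000_000,
    min_donor_loci: int = 5,
    min_donor_frac: float = 0.8,
    max_gap_windows: int = 1,
) -> list[IntrogressionSegment]:
    """Window scan + merge for one NIL, from matrix and informative loci."""
    calls = nil_donor_calls(matrix, loci, nil)
    windows = scan_windows(calls, window_size, min_donor_loci, min_donor_frac)
    return merge_segments(windows, calls, nil=nil, max_gap_windows=max_gap_windows)


def _intersect_two(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s < e:
                out.append((s, e))
    return sorted(out)


def intersect_nils(
    segments_by_nil: Mapping[str, Sequence[IntrogressionSegment]],
    matrix: GenotypeMatrix | None = None,
    loci: Sequence[InformativeLocus] | None = None,
) -> list[CommonIntrogressedRegion]:
    """Intersect introgressed segments across NILs into CIRs.

    For each CIR the per-NIL donor-homozygous locus counts and the
    common SNP set (donor-homozygous in *every* NIL) are computed when
    a matrix and informative loci are supplied.
    """
    if len(segments_by_nil) < 2:
        raise ValueError("need segments from at least two NILs")
    nils = list(segments_by_nil)
    chroms: list[str] = []
    for segs in segments_by_nil.values():
        for seg in segs:
            if seg.chrom not in chroms:
                chroms.append(seg.chrom)
    nil_calls = {}
    if matrix is not None and loci is not None:
        for nil in nils:
            nil_calls[nil] = nil_donor_calls(matrix, loci, nil)
    cirs: list[CommonIntrogressedRegion] = []
    for chrom in chroms:
        common = None
        for nil in nils:
            ivs = sorted(
                (s.start, s.end)
                for s in segments_by_nil[nil]
                if s.chrom == chrom
            )
            common = ivs if common is None else _intersect_two(common, ivs)
            if not common:
                break
        for s, e in common or []:
            per_nil: dict[str, int] = {}
            common_snps: list[InformativeLocus] = []
            if nil_calls:
                masks = {}
                for nil in nils:
                    df = nil_calls[nil]
                    inside = (
                        (df["chrom"] == chrom)
                        & (df["pos"] > s)
                        & (df["pos"] <= e)
                    )
                    masks[nil] = (inside & df["donor"]).to_numpy()
                    per_nil[nil] = int(masks[nil].sum())
                all_donor = np.logical_and.reduce(list(masks.values()))
                loci_arr = list(loci)  # aligned with nil_donor_calls rows
                common_snps = [
                    loci_arr[i] for i in np.nonzero(all_donor)[0]
                ]
            cirs.append(
                CommonIntrogressedRegion(
                    chrom=chrom, start=s, end=e,
                    per_nil_counts=per_nil, common_snps=common_snps,
                )
            )
    return cirs


def segments_to_bed(
    segments: Sequence[IntrogressionSegment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.nil}\t"
                f"{seg.n_donor_loci}\n"
            )


def cirs_to_bed(
    cirs: Sequence[CommonIntrogressedRegion], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for i, cir in enumerate(cirs, 1):
            fh.write(
                f"{cir.chrom}\t{cir.start}\t{cir.end}\tCIR{i}\t{cir.n_common}\n"
            )


def plot_graphical_genotypes(
    windows_by_nil: Mapping[str, pd.DataFrame],
    path: str | Path,
) -> None:
    """Chromosome-scale plot of donor-flagged windows per NIL (optional).

    Requires matplotlib; one horizontal track per NIL and chromosome,
    flagged windows drawn as filled blocks.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms: list[str] = []
    for df in windows_by_nil.values():
        for c in df["chrom"].unique():
            if c not in chroms:
                chroms.append(c)
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 1.2 * len(chroms)), squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        for i, (nil, df) in enumerate(windows_by_nil.items()):
            sub = df[df["chrom"] == chrom]
            ax.broken_barh(
                [(r["start"], r["end"] - r["start"])
                 for _, r in sub[sub["flagged"]].iterrows()],
                (i, 0.8),
                facecolors="firebrick",
            )
            ax.plot([0, sub["end"].max() if not sub.empty else 1], [i, i],
                    color="steelblue", lw=0.5)
        ax.set_yticks([i + 0.4 for i in range(len(windows_by_nil))])
        ax.set_yticklabels(list(windows_by_nil))
        ax.set_title(chrom, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
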