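"""Read-proportion genotyping of multi-sample variant calls.

Builds the integrated SNP/InDel matrix: biallelic sites passing a
mapping-quality filter, each sample classified from its allele depths
by the proportion of reads supporting the alt allele:

* homozygous when one allele holds >= 90% of reads,
* heterozygous when the alt proportion lies in [40%, 60%],
* unclassified otherwise (including depth below the per-sample
  minimum, default 3).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class CallClass(enum.Enum):
    """Per-sample genotype class with its single-letter matrix code."""

    HOM_REF = "l"
    HOM_ALT = "h"
    HET = "e"
    UNCLASSIFIED = "u"

    @classmethod
    def from_code(cls, code: str) -> "CallClass":
        return _BY_CODE[code]


_BY_CODE = {c.value: c for c in CallClass}


@dataclass(frozen=True)
class VariantSite:
    """One biallelic site with per-sample allele depths."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vtype: str  # SNP | InDel
    mq: float | None
    ad_ref: tuple[int, ...]
    ad_alt: tuple[int, ...]
    dp: tuple[int, ...]


def classify_call(
    ad_ref: int,
    ad_alt: int,
    hom_frac: float = 0.90,
    het_low: float = 0.40,
    het_high: float = 0.60,
) -> CallClass:
    """Classify one genotype from its allele depths.

    With p = ad_alt / (ad_ref + ad_alt): HOM_ALT when p >= hom_frac,
    HOM_REF when p <= 1 - hom_frac, HET when het_low <= p <= het_high,
    otherwise UNCLASSIFIED.  Zero total depth is UNCLASSIFIED.
    """
    if ad_ref < 0 or ad_alt < 0:
        raise ValueError("allele depths must be non-negative")
    total = ad_ref + ad_alt
    if total == 0:
        return CallClass.UNCLASSIFIED
    p = ad_alt / total
    if p >= hom_frac:
        return CallClass.HOM_ALT
    if ad_ref / total >= hom_frac:  # symmetric rule, exact at p = 1 - hom_frac
        return CallClass.HOM_REF
    if het_low <= p <= het_high:
        return CallClass.HET
    return CallClass.UNCLASSIFIED


def filter_sites(
    sites: Iterable[VariantSite],
    min_mq: float = 30.0,
) -> Iterator[VariantSite]:
    """Site-level filter: keep sites with MQ strictly greater than min_mq.

    Records without an MQ value pass with a warning (caller-dialect
    tolerance).  Biallelic selection happens at parse time; per-sample
    depth gating happens at classification time, so one low-coverage
    sample never discards the site for the others.
    """
    n_no_mq = 0
    for site in sites:
        if site.mq is None:
            n_no_mq += 1
            yield site
        elif site.mq > min_mq:
            yield site
    if n_no_mq:
        logger.warning("%d sites had no MQ value and passed unfiltered", n_no_mq)


@dataclass
class GenotypeMatrix:
    """Classified calls at retained sites for a set of samples.

    ``sites`` has columns chrom, pos, ref, alt, vtype, mq;
    ``calls`` is aligned row-wise with one single-letter-coded column
    per sample (h = alt-homozygous, l = ref-homozygous, e = het,
    u = unclassified).
    """

    sites: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.calls):
            raise ValueError("sites and calls must be aligned")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    def __len__(self) -> int:
        return len(self.sites)

    def per_chromosome_counts(self) -> pd.DataFrame:
        """Retained-site tally per chromosome and variant type."""
        df = self.sites.groupby(["chrom", "vtype"]).size().unstack(fill_value=0)
        return df

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat(
            [self.sites.reset_index(drop=True), self.calls.reset_index(drop=True)],
            axis=1,
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        site_cols = ["chrom", "pos", "ref", "alt", "vtype", "mq"]
        samples = [c for c in df.columns if c not in site_cols]
        return cls(sites=df[site_cols], calls=df[samples])


def _iter_vcf_sites(
    vcf_path: str | Path, samples: Sequence[str] | None
) -> tuple[list[str], Iterator[VariantSite]]:
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    header_samples = list(vcf.samples)
    if samples is None:
        samples = header_samples
    missing = [s for s in samples if s not in header_samples]
    if missing:
        raise KeyError(
            f"samples {missing} not in VCF header; header has {header_samples}"
        )
    idx = [header_samples.index(s) for s in samples]

    def gen() -> Iterator[VariantSite]:
        n_multi = n_bad = 0
        for v in vcf:
            try:
                if len(v.ALT) != 1:
                    n_multi += 1
                    continue
                ref, alt = v.REF, v.ALT[0]
                vtype = "SNP" if len(ref) == 1 and len(alt) == 1 else "InDel"
                mq = v.INFO.get("MQ")
                ad = v.format("AD")
                dp = v.format("DP")
                if ad is None:
                    n_bad += 1
                    logger.warning("%s:%d has no AD field; skipped", v.CHROM, v.POS)
                    continue
                ad = np.asarray(ad)
                ad_ref = tuple(max(0, int(ad[i, 0])) for i in idx)
                ad_alt = tuple(max(0, int(ad[i, 1])) for i in idx)
                if dp is not None:
                    dparr = np.asarray(dp).reshape(len(header_samples), -1)
                    dps = tuple(max(0, int(dparr[i, 0])) for i in idx)
                else:
                    dps = tuple(r + a for r, a in zip(ad_ref, ad_alt))
                yield VariantSite(
                    chrom=v.CHROM, pos=v.POS, ref=ref, alt=alt, vtype=vtype,
                    mq=float(mq) if mq is not None else None,
                    ad_ref=ad_ref, ad_alt=ad_alt, dp=dps,
                )
            except (ValueError, TypeError, IndexError) as exc:
                n_bad += 1
                logger.warning("malformed record at %s:%s skipped (%s)", v.CHROM, v.POS, exc)
        if n_multi:
            logger.info("dropped %d multi-allelic records", n_multi)
        if n_bad:
            logger.warning("skipped %d malformed records", n_bad)

    return list(samples), gen()


def build_matrix(
    vcf_path: str | Path,
    samples: Sequence[str] | None = None,
    min_depth: int = 3,
    min_mq: float = 30.0,
    hom_frac: float = 0.90,
    het_low: float = 0.40,
    het_high: float = 0.60,
) -> GenotypeMatrix:
    """Read a VCF and build the classified genotype matrix.

    Sites are retained when biallelic with MQ > ``min_mq``; each
    sample's call at a retained site is classified from AD only where
    its DP >= ``min_depth``, else it is unclassified.
    """
    sample_names, site_iter = _iter_vcf_sites(vcf_path, samples)
    rows = []
    call_rows = []
    for site in filter_sites(site_iter, min_mq=min_mq):
        rows.append(
            (site.chrom, site.pos, site.ref, site.alt, site.vtype,
             site.mq if site.mq is not None else np.nan)
        )
        codes = []
        for r, a, d in zip(site.ad_ref, site.ad_alt, site.dp):
            if d < min_depth:
                codes.append(CallClass.UNCLASSIFIED.value)
            else:
                codes.append(
                    classify_call(r, a, hom_frac, het_low, het_high).value
                )
        call_rows.append(codes)
    sites_df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "vtype", "mq"]
    )
    calls_df = pd.DataFrame(call_rows, columns=sample_names, dtype=str)
    if not rows:
        calls_df = pd.DataFrame(columns=sample_names, dtype=str)
        logger.info("no sites retained: empty matrix")
    return GenotypeMatrix(sites=sites_df, calls=calls_df)
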