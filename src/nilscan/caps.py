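"""In-silico CAPS marker design.

A CAPS (cleaved amplified polymorphic sequence) marker exploits a SNP
that creates or destroys a restriction-enzyme recognition site: the
two alleles of a PCR amplicon then digest into different fragment
patterns that separate on a gel.  This module searches IUPAC-
degenerate recognition sites on both strands, finds enzymes whose site
set differs between the two alleles because of the polymorphism, and
predicts per-allele (and heterozygote) digestion fragment sizes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition sequence and top-strand cut offset.

    ``cut_offset`` is the number of bases between the 5' end of the
    recognition site and the top-strand cut (e.g. 1 for G^AATTC).
    Palindromicity is derived from the recognition sequence, never
    assumed.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError(f"{self.name}: empty recognition sequence")
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC characters {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut offset outside recognition site")

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.recognition.upper()) == self.recognition.upper()


def load_enzymes(path: str | Path | None = None) -> list[Enzyme]:
    """Load an enzyme catalogue TSV (name, recognition, cut_offset).

    Without a path, the packaged catalogue of ~30 common blunt/sticky
    double-strand cutters is used.
    """
    if path is None:
        ref = resources.files("nilscan.data") / "enzymes.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    enzymes = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        enzymes.append(
            Enzyme(
                name=row["name"],
                recognition=row["recognition"].upper(),
                cut_offset=int(row["cut_offset"]),
            )
        )
    return enzymes


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in "ACGTN":
            raise ValueError(f"invalid character {ch!r} at offset {i}")
    return seq


def _matches_at(seq: str, pattern: str, i: int) -> bool:
    # An N in the *sequence* never matches (conservative design);
    # degenerate bases are meaningful only in the pattern.
    for j, pch in enumerate(pattern):
        sch = seq[i + j]
        if sch == "N" or sch not in IUPAC[pch]:
            return False
    return True


def find_sites(seq: str, enzyme: Enzyme) -> list[tuple[int, str]]:
    """All recognition sites on either strand, in top-strand coordinates.

    Returns (start, strand) pairs, 0-based; minus-strand matches are
    positions where the reverse complement of the recognition sequence
    occurs on the top strand.  Palindromic enzymes report each position
    once (strand '+').  Overlapping sites are all reported.
    """
    seq = _validate_seq(seq)
    pat = enzyme.recognition.upper()
    k = len(pat)
    out: list[tuple[int, str]] = []
    rc = revcomp(pat)
    palindromic = enzyme.is_palindromic
    for i in range(len(seq) - k + 1):
        if _matches_at(seq, pat, i):
            out.append((i, "+"))
        elif not palindromic and _matches_at(seq, rc, i):
            out.append((i, "-"))
    return out


def cut_positions(seq: str, enzyme: Enzyme, strand: str = "top") -> list[int]:
    """Cut coordinates (in top-strand coordinates) for every site.

    On the top strand, a plus-strand site starting at i cuts at
    i + cut_offset and a minus-strand site at i + site_length -
    cut_offset; the bottom-strand cuts are mirrored within the site.
    Fragment sizes are reported from top-strand cuts, the convention
    of standard digest viewers; for staggered cutters the two strands
    differ by the overhang length.
    """
    if strand not in ("top", "bottom"):
        raise ValueError("strand must be 'top' or 'bottom'")
    k = enzyme.site_length
    cuts = set()
    for i, site_strand in find_sites(seq, enzyme):
        plus_cut = (site_strand == "+") == (strand == "top")
        cuts.add(i + enzyme.cut_offset if plus_cut else i + k - enzyme.cut_offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest_fragments(seq: str, enzyme: Enzyme) -> list[int]:
    """Fragment sizes (descending) from a complete digest of ``seq``."""
    cuts = cut_positions(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    return sorted(
        (bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)),
        reverse=True,
    )


@dataclass(frozen=True)
class CapsCandidate:
    """An enzyme whose digestion pattern distinguishes the two alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str
    enzyme: Enzyme
    allele_with_site: str  # "ref" | "alt" | "both"
    amplicon_start: int  # 0-based offset of the amplicon in the flank
    fragments_ref: tuple[int, ...]
    fragments_alt: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.fragments_ref == self.fragments_alt:
            raise ValueError("candidate must distinguish the alleles")

    @property
    def fragments_het(self) -> tuple[int, ...]:
        """Heterozygote band pattern: union of both allele patterns."""
        return tuple(
            sorted(set(self.fragments_ref) | set(self.fragments_alt), reverse=True)
        )


def substitute(flank: str, offset: int, old: str, new: str) -> str:
    """Replace allele ``old`` with ``new`` at ``offset`` in the flank."""
    if flank[offset : offset + len(old)].upper() != old.upper():
        raise ValueError(
            f"flank does not carry allele {old!r} at offset {offset}"
        )
    return flank[:offset] + new + flank[offset + len(old) :]


def _site_intervals(seq: str, enzyme: Enzyme) -> set[tuple[int, int]]:
    k = enzyme.site_length
    return {(i, i + k) for i, _ in find_sites(seq, enzyme)}


def differential_digest(
    flank: str,
    snp_offset: int,
    ref_allele: str,
    alt_allele: str,
    enzymes: Sequence[Enzyme],
    chrom: str = ".",
    pos: int | None = None,
    amplicon_halfwidth: int = 150,
) -> list[CapsCandidate]:
    """Find enzymes turned on/off by the polymorphism.

    For each enzyme the recognition-site sets of the ref- and
    alt-substituted flank are compared; the enzyme is a candidate when
    the sets differ *and* a differing site overlaps the variant (the
    polymorphism itself must cause the difference).  Fragment sizes are
    then predicted on an amplicon of +-``amplicon_halfwidth`` bp around
    the variant.
    """
    if ref_allele.upper() == alt_allele.upper():
        raise ValueError("ref and alt alleles are identical")
    flank = _validate_seq(flank)
    if not 0 <= snp_offset < len(flank):
        raise ValueError("snp_offset outside the flank")
    ref_seq = substitute(flank, snp_offset, ref_allele, ref_allele.upper())
    alt_seq = substitute(flank, snp_offset, ref_allele, alt_allele.upper())

    a_start = max(0, snp_offset - amplicon_halfwidth)
    a_end_ref = min(len(ref_seq), snp_offset + len(ref_allele) + amplicon_halfwidth)
    a_end_alt = min(len(alt_seq), snp_offset + len(alt_allele) + amplicon_halfwidth)
    amp_ref = ref_seq[a_start:a_end_ref]
    amp_alt = alt_seq[a_start:a_end_alt]

    var_ref = (snp_offset, snp_offset + len(ref_allele))
    var_alt = (snp_offset, snp_offset + len(alt_allele))
    out = []
    for enz in enzymes:
        sites_ref = _site_intervals(ref_seq, enz)
        sites_alt = _site_intervals(alt_seq, enz)
        if sites_ref == sites_alt:
            continue
        only_ref = sites_ref - sites_alt
        only_alt = sites_alt - sites_ref
        hits_var = any(
            s < var_ref[1] and var_ref[0] < e for s, e in only_ref
        ) or any(s < var_alt[1] and var_alt[0] < e for s, e in only_alt)
        if not hits_var:
            continue
        frags_ref = tuple(digest_fragments(amp_ref, enz))
        frags_alt = tuple(digest_fragments(amp_alt, enz))
        if frags_ref == frags_alt:
            continue
        if only_ref and only_alt:
            allele_with_site = "both"
        elif only_ref:
            allele_with_site = "ref"
        else:
            allele_with_site = "alt"
        out.append(
            CapsCandidate(
                chrom=chrom, pos=pos if pos is not None else snp_offset + 1,
                ref=ref_allele.upper(), alt=alt_allele.upper(), enzyme=enz,
                allele_with_site=allele_with_site, amplicon_start=a_start,
                fragments_ref=frags_ref, fragments_alt=frags_alt,
            )
        )
    return out


def predict_fragments(
    amplicon: str,
    enzyme: Enzyme,
    alleles: dict[str, tuple[int, str, str]] | None = None,
) -> dict[str, tuple[int, ...]]:
    """Digestion patterns per genotype class of an amplicon.

    Without ``alleles``, digests the amplicon as-is under key "amplicon".
    With ``alleles`` = {"ref": (offset, old, new), "alt": (...)}, returns
    patterns for "ref", "alt" and the heterozygote "het" (the union of
    both allele patterns, as seen as gel bands).
    """
    amplicon = _validate_seq(amplicon)
    if alleles is None:
        return {"amplicon": tuple(digest_fragments(amplicon, enzyme))}
    out: dict[str, tuple[int, ...]] = {}
    for name in ("ref", "alt"):
        offset, old, new = alleles[name]
        seq = substitute(amplicon, offset, old, new)
        out[name] = tuple(digest_fragments(seq, enzyme))
    out["het"] = tuple(sorted(set(out["ref"]) | set(out["alt"]), reverse=True))
    return out


def candidates_to_tsv(
    candidates: Iterable[CapsCandidate], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tenzyme\trecognition\tallele_with_site\t"
            "fragments_hh\tfragments_ll\tfragments_hl\n"
        )
        for c in candidates:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.enzyme.name}\t"
                f"{c.enzyme.recognition}\t{c.allele_with_site}\t"
                f"{','.join(map(str, c.fragments_alt))}\t"
                f"{','.join(map(str, c.fragments_ref))}\t"
                f"{','.join(map(str, c.fragments_het))}\n"
            )
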