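"""Site-pattern introgression statistics for a species quartet.

Given four aligned sequences ordered (S1, S2, S3, O) with assumed
phylogeny ((S1,S2),S3) plus outgroup O, the parsimony-informative site
patterns are ABBA, BABA and BBAA, where A and B stand for any two
distinct nucleotides and, e.g., BBAA means S1 and S2 share one
nucleotide while S3 and O share another.  Under the species tree with
no gene flow the two mismatching patterns ABBA and BABA are equally
probable; an excess of one signals gene flow between a nonsister pair:

    D = (n_ABBA - n_BABA) / (n_ABBA + n_BABA)

The counts also yield a moment estimator of the introgression
probability under a symmetric hybrid-speciation model:

    phi_hat = (n_BBAA - n_BABA) / (n_BBAA - 2 n_BABA + n_ABBA)

These genome-wide averages ignore the across-locus genealogical
variance that full-likelihood MSci inference exploits; they detect
nonsister gene flow but cannot resolve its direction, nor gene flow
between sister species.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SitePatternCounts", "count_site_patterns", "d_statistic", "hyde_phi"]

_NUCS = frozenset("ACGT")


@dataclass
class SitePatternCounts:
    n_abba: int = 0
    n_baba: int = 0
    n_bbaa: int = 0


def count_site_patterns(sequences) -> SitePatternCounts:
    """Count ABBA/BABA/BBAA columns in four equal-length sequences
    ordered (S1, S2, S3, O).

    Only biallelic columns with a clean 2/2 split over A/C/G/T count;
    sites with gaps, ambiguity codes or more than two states are
    ignored.
    """
    seqs = [str(s).upper() for s in sequences]
    if len(seqs) != 4:
        raise ValueError(f"need exactly 4 sequences, got {len(seqs)}")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must have equal length")
    counts = SitePatternCounts()
    for s1, s2, s3, o in zip(*seqs):
        col = (s1, s2, s3, o)
        if not _NUCS.issuperset(col) or len(set(col)) != 2:
            continue
        if s1 == s2 and s3 == o and s1 != s3:
            counts.n_bbaa += 1
        elif s1 == o and s2 == s3 and s1 != s2:
            counts.n_abba += 1
        elif s2 == o and s1 == s3 and s1 != s2:
            counts.n_baba += 1
    return counts


def d_statistic(counts: SitePatternCounts) -> float | None:
    """ABBA-BABA D statistic; None when both mismatching counts are
    zero (undefined)."""
    denom = counts.n_abba + counts.n_baba
    if denom == 0:
        return None
    return (counts.n_abba - counts.n_baba) / denom


def hyde_phi(counts: SitePatternCounts) -> float | None:
    """Moment estimator of the introgression probability from the three
    informative site-pattern counts; None when the denominator
    vanishes.  Can be biased when the symmetry assumptions behind it
    (equal parental divergence times and population sizes) fail."""
    denom = counts.n_bbaa - 2 * counts.n_baba + counts.n_abba
    if denom == 0:
        return None
    return (counts.n_bbaa - counts.n_baba) / denom
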