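"""Degenerate promoter-motif scanning and per-module enrichment.

Motifs are IUPAC 6-8-mers (ABRE ACGTGKC, DRE/CRT RCCGAC(A), NACR
CATGTG, GCC-box GCCGCC, ...). Scanning is case-insensitive, counts all
(overlapping) start offsets, and optionally includes the reverse
strand; enrichment per module is hypergeometric on motif presence with
Benjamini-Hochberg FDR across all (module, motif) pairs jointly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from berrynet.datatypes import (
    IUPAC_CODES,
    ModuleAssignment,
    MotifSet,
    PromoterSet,
    ValidationError,
    reverse_complement,
    validate_iupac,
)
from berrynet.stats import EnrichmentRecord, bh_fdr, hypergeometric_upper


def iupac_matcher(motif: str) -> re.Pattern:
    """Compile an IUPAC motif to an overlap-counting regex.

    Each motif position becomes the character class of its concrete
    bases; an 'N' in the *sequence* is treated as unknown and matches
    only a motif 'N' (which accepts anything). The pattern is wrapped in
    a lookahead so every start offset is counted, overlaps included.
    """
    motif = validate_iupac(motif)
    parts = []
    for ch in motif:
        bases = sorted(IUPAC_CODES[ch])
        if ch == "N":
            bases.append("N")
        parts.append("[" + "".join(bases) + "]")
    return re.compile("(?=" + "".join(parts) + ")")


def count_matches(matcher: re.Pattern, sequence: str) -> int:
    return sum(1 for _ in matcher.finditer(sequence.upper()))


@dataclass
class MotifMatchTable:
    """Per-(gene, motif) match counts and presence flags."""

    counts: pd.DataFrame  # genes x motifs, integer match counts
    strands: str = "both"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("match counts must be nonnegative")

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= 1

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def motifs(self) -> list[str]:
        return list(self.counts.columns)


def scan_promoters(
    promoters: PromoterSet, motifs: MotifSet, strands: str = "both"
) -> MotifMatchTable:
    """Slide every motif over every promoter, counting all start offsets.

    ``strands='both'`` additionally scans the reverse complement of each
    promoter; counts sum over strands and presence is the OR.
    """
    if strands not in ("forward", "both"):
        raise ValidationError(f"strands must be 'forward' or 'both', got {strands!r}")
    matchers = {m: iupac_matcher(m) for m in motifs}
    genes = promoters.gene_ids
    counts = pd.DataFrame(0, index=genes, columns=list(motifs), dtype=int)
    for gid in genes:
        seq = promoters.sequences[gid]
        rc = reverse_complement(seq) if strands == "both" else None
        for motif, matcher in matchers.items():
            c = count_matches(matcher, seq)
            if rc is not None:
                c += count_matches(matcher, rc)
            counts.loc[gid, motif] = c
    return MotifMatchTable(counts, strands=strands)


def module_cre_enrichment(
    match: MotifMatchTable,
    modules: ModuleAssignment,
    background: set[str] | None = None,
    fdr_threshold: float = 0.01,
) -> list[EnrichmentRecord]:
    """Hypergeometric motif-presence enrichment per (module, motif).

    k = module genes carrying the motif, n = module size, K = background
    carriers, N = background size. BH FDR is applied across all
    (module, motif) pairs jointly; a pair is enriched when fdr <
    ``fdr_threshold``. The background defaults to all scanned genes.
    """
    if background is None:
        background = set(match.gene_ids)
    scanned = set(match.gene_ids)
    missing_bg = sorted(background - scanned)
    if missing_bg:
        raise ValidationError(
            f"background gene(s) lack promoters: {missing_bg[:5]}"
        )
    presence = match.presence.loc[sorted(background)]
    N = len(background)
    records: list[tuple[str, str, int, int, int]] = []
    for mod in modules.module_ids:
        members = [g for g in modules.members(mod)]
        outside = sorted(set(members) - background)
        if outside:
            raise ValidationError(
                f"module {mod!r} gene(s) missing from background/promoters: "
                f"{outside[:5]}"
            )
        n = len(members)
        sub = presence.loc[members]
        for motif in match.motifs:
            k = int(sub[motif].sum())
            K = int(presence[motif].sum())
            records.append((mod, motif, k, n, K))
    pvals = [hypergeometric_upper(k, n, K, N) for _, _, k, n, K in records]
    fdrs = bh_fdr(pvals) if pvals else []
    out = []
    for (mod, motif, k, n, K), p, fdr in zip(records, pvals, fdrs):
        out.append(
            EnrichmentRecord(
                set_id=mod, annotation_id=motif, k=k, n=n, K=K, N=N,
                p=float(p), fdr=float(fdr), enriched=bool(fdr < fdr_threshold),
            )
        )
    return out


def enrichment_table(records: list[EnrichmentRecord],
                     motifs: MotifSet | None = None) -> pd.DataFrame:
    """Flatten enrichment records to the export table layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "module": r.set_id,
                "motif": r.annotation_id,
                "label": motifs.label(r.annotation_id) if motifs else "",
                "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "p": r.p, "fdr": r.fdr, "score": r.score,
                "enriched": r.enriched,
            }
        )
    cols = ["module", "motif", "label", "k", "n", "K", "N", "p", "fdr",
            "score", "enriched"]
    return pd.DataFrame(rows, columns=cols)
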