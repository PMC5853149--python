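"""Somatic-mutation burden in motif instances of tapRNA loci versus
background loci, and the mutation/expression-change concordance join.

The unit of the enrichment test is the motif site (mutated yes/no), so the
2x2 Fisher test is free of per-sample dependence; raw mutation counts are
reported descriptively. Duplicate mutations (same sample, position, alt)
are collapsed before counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .models import Interval, MutationRecord
from .motifs import MotifHit


@dataclass
class MotifMutationSummary:
    set_label: str
    n_motif_sites: int
    n_mutated_sites: int
    n_mutations: int
    n_cancer_types: int
    per_site: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __add__(self, other: "MotifMutationSummary") -> "MotifMutationSummary":
        per_site = pd.concat([self.per_site, other.per_site],
                             ignore_index=True)
        cancers = set()
        if not per_site.empty:
            for types in per_site["cancer_types"]:
                cancers.update(types)
        return MotifMutationSummary(
            set_label=f"{self.set_label}+{other.set_label}",
            n_motif_sites=self.n_motif_sites + other.n_motif_sites,
            n_mutated_sites=self.n_mutated_sites + other.n_mutated_sites,
            n_mutations=self.n_mutations + other.n_mutations,
            n_cancer_types=len(cancers),
            per_site=per_site,
        )


def dedupe_mutations(mutations: Iterable[MutationRecord],
                     ) -> list[MutationRecord]:
    """Collapse duplicate (sample, chrom, pos, alt) records."""
    seen, out = set(), []
    for m in mutations:
        key = (m.sample_id, m.chrom, m.pos, m.alt)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def motif_mutation_counts(motif_hits: Sequence[MotifHit],
                          mutations: Sequence[MutationRecord],
                          set_label: str = "test") -> MotifMutationSummary:
    """Count mutated motif sites and (mutation, site) incidences.

    A site is mutated iff >= 1 deduplicated mutation position falls inside
    its interval; cancer types are distinct labels among contributing
    mutations.
    """
    muts = dedupe_mutations(mutations)
    by_chrom: dict[str, list[MutationRecord]] = {}
    for m in muts:
        by_chrom.setdefault(m.chrom, []).append(m)
    rows = []
    cancers: set[str] = set()
    n_mutations = 0
    n_mutated = 0
    for hit in motif_hits:
        iv = hit.interval
        inside = [m for m in by_chrom.get(iv.chrom, [])
                  if iv.start <= m.pos < iv.end]
        site_cancers = sorted({m.cancer_type for m in inside})
        cancers.update(site_cancers)
        n_mutations += len(inside)
        n_mutated += bool(inside)
        rows.append((hit.pwm_id, iv.chrom, iv.start, iv.end,
                     len(inside), tuple(site_cancers)))
    per_site = pd.DataFrame(
        rows, columns=["pwm_id", "chrom", "start", "end", "n_mutations",
                       "cancer_types"])
    return MotifMutationSummary(
        set_label=set_label, n_motif_sites=len(motif_hits),
        n_mutated_sites=n_mutated, n_mutations=n_mutations,
        n_cancer_types=len(cancers), per_site=per_site)


def mutation_rate_test(summary_test: MotifMutationSummary,
                       summary_background: MotifMutationSummary,
                       ) -> tuple[float, float]:
    """One-sided Fisher exact test of site-mutation rates (test >
    background); returns (odds ratio, p)."""
    if summary_test.n_motif_sites == 0 or summary_background.n_motif_sites == 0:
        raise ValueError("both summaries need motif sites")
    table = [
        [summary_test.n_mutated_sites,
         summary_test.n_motif_sites - summary_test.n_mutated_sites],
        [summary_background.n_mutated_sites,
         summary_background.n_motif_sites - summary_background.n_mutated_sites],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def taprna_locus(promoter: Interval, span: Interval) -> list[Interval]:
    """The scanned locus: promoter window union transcript span."""
    if promoter.chrom == span.chrom and promoter.overlaps(span) or (
            promoter.chrom == span.chrom
            and (promoter.end == span.start or span.end == promoter.start)):
        lo = min(promoter.start, span.start)
        hi = max(promoter.end, span.end)
        return [Interval(promoter.chrom, lo, hi, span.strand)]
    return [promoter, span]


def hits_in_loci(hits: Sequence[MotifHit],
                 loci: Sequence[Interval]) -> list[MotifHit]:
    """Motif hits overlapping any locus interval."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in loci:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    return [h for h in hits
            if any(h.interval.overlaps(iv)
                   for iv in by_chrom.get(h.interval.chrom, []))]


def mutation_expression_join(mutated_taprnas: pd.DataFrame,
                             expression_change_table: pd.DataFrame,
                             ) -> pd.DataFrame:
    """Inner join of mutated tapRNAs with significant expression changes in
    the matching cancer type.

    ``mutated_taprnas`` columns: taprna_id, motif_class, cancer_type.
    ``expression_change_table`` columns: taprna_id, cancer_type,
    significant (bool), and optionally a direction/effect column carried
    through. One output row per (tapRNA, motif_class, cancer_type).
    """
    sig = expression_change_table[expression_change_table["significant"]]
    joined = mutated_taprnas.merge(sig, on=["taprna_id", "cancer_type"],
                                   how="inner")
    return (joined.drop_duplicates(["taprna_id", "motif_class",
                                    "cancer_type"])
            .reset_index(drop=True))
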