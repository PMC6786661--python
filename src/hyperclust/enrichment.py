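"""APOBEC motif enrichment of mutation sets.

The statistic compares how often mutations fall in a signature motif (for
A3A-like deamination, ytCa with the mutated C capitalized; y = C/T,
r = A/G, w = A/T) with how often the motif occurs in the local sequence
context. The context is the 41-nucleotide window centred on each mutated
residue, which absorbs local composition and short-range enzyme-scanning
preferences:

    enrichment = [mutations(motif) * context(base)] /
                 [mutations(base)  * context(motif)]

where ``mutations(base)`` are all C->T changes (pooled with their G->A
reverse complements), ``mutations(motif)`` the subset matching the motif on
the mutated strand, ``context(motif)`` the motif occurrences (both strands)
in the windows of all qualifying sites, and ``context(base)`` the C+G count
in the same windows. Significance comes from a one-sided Fisher exact test
of the mutation tally against the context tally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .detect import Cluster, scattered_mutations
from .io import GenomeModel, MutationRecord

IUPAC: Mapping[str, str] = {
    "a": "A", "c": "C", "g": "G", "t": "T",
    "r": "AG", "y": "CT", "s": "CG", "w": "AT",
    "k": "GT", "m": "AC", "b": "CGT", "d": "AGT",
    "h": "ACT", "v": "ACG", "n": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn", "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

DEFAULT_WINDOW = 20
#: Decision rule for calling a set "APOBEC-enriched" (configurable, not a
#: literature constant): enrichment above this with p below alpha.
DEFAULT_ENRICHED_MIN = 2.0
DEFAULT_ENRICHED_ALPHA = 0.05


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """An IUPAC motif with exactly one uppercase (mutated) position."""

    text: str

    def __post_init__(self) -> None:
        uppers = [i for i, ch in enumerate(self.text) if ch.isupper()]
        if len(uppers) != 1:
            raise ValueError(f"motif {self.text!r} must mark exactly one mutated position (uppercase)")
        for ch in self.text.lower():
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r} in motif {self.text!r}")

    @property
    def mutated_index(self) -> int:
        return next(i for i, ch in enumerate(self.text) if ch.isupper())

    @property
    def mutated_base(self) -> str:
        return self.text[self.mutated_index].upper()

    @property
    def sets(self) -> tuple[str, ...]:
        return tuple(IUPAC[ch.lower()] for ch in self.text)

    def reverse_complement(self) -> "Motif":
        return Motif(reverse_complement(self.text))

    def regex(self) -> "re.Pattern[str]":
        # lookahead so overlapping occurrences are all counted
        body = "".join(f"[{IUPAC[ch.lower()]}]" for ch in self.text)
        return re.compile(f"(?={body})")

    def matches_at(self, seq: str, index: int) -> bool:
        """Does the motif match ``seq`` with its mutated position at ``index``?"""
        start = index - self.mutated_index
        if start < 0 or start + len(self.text) > len(seq):
            return False
        return all(seq[start + i] in allowed for i, allowed in enumerate(self.sets))


@dataclass(frozen=True)
class EnrichmentResult:
    """Tallies and the context-normalized enrichment ratio for one motif."""

    motif: str
    n_motif_mut: int
    n_base_mut: int
    ctx_motif: int
    ctx_base: int
    enrichment: float | None
    p: float | None

    @property
    def defined(self) -> bool:
        return self.enrichment is not None

    def is_enriched(
        self, min_enrichment: float = DEFAULT_ENRICHED_MIN, alpha: float = DEFAULT_ENRICHED_ALPHA
    ) -> bool:
        return self.defined and self.enrichment > min_enrichment and self.p < alpha


def motif_enrichment(
    mutations: Sequence[MutationRecord],
    genome: GenomeModel,
    motif: str = "ytCa",
    change: tuple[str, str] = ("C", "T"),
    window: int = DEFAULT_WINDOW,
) -> EnrichmentResult:
    """Context-normalized motif enrichment of a mutation set.

    Pools the forward motif at ``change`` sites (default C->T) with the
    reverse-complement motif at complementary (G->A) sites. Windows are
    ``+/- window`` bases around every qualifying mutated site, truncated at
    chromosome ends; N bases never match. A zero denominator (no qualifying
    mutations, or no motif occurrence in context) leaves the ratio
    undefined (``enrichment is None``) rather than propagating NaN.
    """
    fwd = Motif(motif)
    if fwd.mutated_base != change[0].upper():
        raise ValueError(
            f"motif {motif!r} marks {fwd.mutated_base}, but change is {change[0]}->{change[1]}"
        )
    rev = fwd.reverse_complement()
    fwd_re, rev_re = fwd.regex(), rev.regex()
    ref_f, alt_f = change[0].upper(), change[1].upper()
    ref_r, alt_r = reverse_complement(ref_f), reverse_complement(alt_f)
    base_f, base_r = fwd.mutated_base, rev.mutated_base

    n_base_mut = n_motif_mut = ctx_motif = ctx_base = 0
    for mut in mutations:
        if mut.ref == ref_f and mut.alt == alt_f:
            site_motif = fwd
        elif mut.ref == ref_r and mut.alt == alt_r:
            site_motif = rev
        else:
            continue
        n_base_mut += 1
        seq, offset = genome.window(mut.chrom, mut.pos, window)
        if site_motif.matches_at(seq, offset):
            n_motif_mut += 1
        ctx_base += seq.count(base_f) + seq.count(base_r)
        ctx_motif += len(fwd_re.findall(seq)) + len(rev_re.findall(seq))

    if n_base_mut == 0 or ctx_motif == 0 or ctx_base == 0:
        return EnrichmentResult(motif, n_motif_mut, n_base_mut, ctx_motif, ctx_base, None, None)
    enrichment = (n_motif_mut * ctx_base) / (n_base_mut * ctx_motif)
    _, p = stats.fisher_exact(
        [[n_motif_mut, n_base_mut - n_motif_mut], [ctx_motif, ctx_base - ctx_motif]],
        alternative="greater",
    )
    return EnrichmentResult(motif, n_motif_mut, n_base_mut, ctx_motif, ctx_base, enrichment, float(p))


def stratified_enrichment(
    mutations: Sequence[MutationRecord],
    clusters: Sequence[Cluster],
    genome: GenomeModel,
    motif: str = "ytCa",
    change: tuple[str, str] = ("C", "T"),
    window: int = DEFAULT_WINDOW,
) -> dict[str, EnrichmentResult]:
    """Enrichment for the all / clustered / scattered strata of one catalog.

    ``scattered`` are mutations in no cluster; with zero clusters the
    clustered stratum is undefined and scattered equals all.
    """
    clustered = [m for cl in clusters for m in cl.mutations]
    scattered = scattered_mutations(mutations, clusters)
    return {
        "all": motif_enrichment(mutations, genome, motif, change, window),
        "clustered": motif_enrichment(clustered, genome, motif, change, window),
        "scattered": motif_enrichment(scattered, genome, motif, change, window),
    }


def enrichment_table(results: Mapping[str, Mapping[str, EnrichmentResult]]) -> "pd.DataFrame":
    """Long-format table: one row per sample x stratum (sum_all-style layout)."""
    import pandas as pd

    rows = []
    for sample_id, strata in results.items():
        for stratum, res in strata.items():
            rows.append(
                {
                    "sample_id": sample_id,
                    "stratum": f"sum_{stratum}" if stratum in {"all", "cluster", "clustered", "scattered"} else stratum,
                    "motif": res.motif,
                    "n_motif_mut": res.n_motif_mut,
                    "n_base_mut": res.n_base_mut,
                    "ctx_motif": res.ctx_motif,
                    "ctx_base": res.ctx_base,
                    "enrichment": res.enrichment,
                    "p_value": res.p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "stratum",
            "motif",
            "n_motif_mut",
            "n_base_mut",
            "ctx_motif",
            "ctx_base",
            "enrichment",
            "p_value",
        ],
    )
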