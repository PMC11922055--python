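"""Codon-composition statistics for gene sets.

Per-gene codon frequencies against a global background, within-amino-acid-
family representation skew, the U/A- versus C/G-rich Leu/Ser codon classes,
and adjacent amino-acid (dipeptide) frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .synthetic import SENSE_CODONS, STOP_CODONS, TranscriptGene

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid over the 61 sense codons
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)

UA_RICH_LEU = frozenset({"TTA", "TTG", "CTA", "CTT"})
CG_RICH_LEU = frozenset({"CTC", "CTG"})
UA_RICH_SER = frozenset({"TCA", "TCT", "AGT"})
CG_RICH_SER = frozenset({"TCC", "TCG", "AGC"})


@dataclass
class CodonUsage:
    """Frequencies over the 61 sense codons (sum to 1) with provenance."""

    freqs: pd.Series
    gene_set_id: str = ""
    n_genes: int = 0


def _validate_cds(gene: TranscriptGene) -> list[str]:
    seq = gene.cds_sequence
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length not divisible by 3 for {gene.gene_id}")
    codons = gene.codons
    if codons[-1] not in STOP_CODONS:
        raise ValueError(f"CDS does not end with a stop codon: {gene.gene_id}")
    body = codons[:-1]
    for c in body:
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon in {gene.gene_id}")
    return body


def codon_usage(cds_set, gene_set_id: str = "", pooled: bool = False) -> CodonUsage:
    """Codon usage of a CDS set: per-gene frequency vectors (terminal stop
    excluded) averaged unweighted across genes, so long genes do not
    dominate.  ``pooled=True`` instead pools codon counts over the set."""
    genes = list(cds_set.genes) if hasattr(cds_set, "genes") else list(cds_set)
    if not genes:
        raise ValueError("empty CDS set")
    index = pd.Index(SENSE_CODONS, name="codon")
    if pooled:
        total = pd.Series(0.0, index=index)
        for g in genes:
            body = _validate_cds(g)
            total = total.add(pd.Series(body).value_counts(), fill_value=0.0)
        total = total.reindex(index, fill_value=0.0)
        freqs = total / total.sum()
    else:
        acc = pd.Series(0.0, index=index)
        for g in genes:
            body = _validate_cds(g)
            counts = pd.Series(body).value_counts().reindex(index, fill_value=0.0)
            acc += counts / counts.sum()
        freqs = acc / len(genes)
    return CodonUsage(freqs=freqs, gene_set_id=gene_set_id, n_genes=len(genes))


def family_relative(usage: CodonUsage) -> pd.DataFrame:
    """Family-relative representation r(c) = f(c) / sum of f over the codon's
    amino-acid family; families with zero total frequency are omitted."""
    rows = []
    fam_totals: dict[str, float] = {}
    for c in SENSE_CODONS:
        fam_totals[GENETIC_CODE[c]] = fam_totals.get(GENETIC_CODE[c], 0.0) + usage.freqs[c]
    for c in SENSE_CODONS:
        aa = GENETIC_CODE[c]
        if fam_totals[aa] <= 0:
            continue
        rows.append({"codon": c, "amino_acid": aa,
                     "frequency": usage.freqs[c],
                     "r": usage.freqs[c] / fam_totals[aa]})
    return pd.DataFrame(rows)


def skew(set_usage: CodonUsage, background_usage: CodonUsage) -> pd.DataFrame:
    """Within-family representation skew of a gene set against a background:
    skew = r_set - r_background per codon (zero-sum within each family).
    Absolute frequencies of both usages are carried along for the
    set-vs-background frequency comparison."""
    rs = family_relative(set_usage).rename(columns={"r": "r_set", "frequency": "f_set"})
    rb = family_relative(background_usage).rename(
        columns={"r": "r_background", "frequency": "f_background"})
    merged = rs.merge(rb[["codon", "r_background", "f_background"]], on="codon")
    merged["skew"] = merged["r_set"] - merged["r_background"]
    return merged


def classify_leu_ser(codon: str) -> str:
    """U/A-rich vs C/G-rich classification of Leu/Ser codons.

    The stalling-prone Leu codons (UUA, UUG, CUA, CUU) are U/A-rich; CUC and
    CUG are C/G-rich; Ser codons are classified analogously by the GC content
    of their variable positions.  Everything else is 'other'.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not a codon: {codon!r}")
    if codon in UA_RICH_LEU or codon in UA_RICH_SER:
        return "UA_rich"
    if codon in CG_RICH_LEU or codon in CG_RICH_SER:
        return "CG_rich"
    return "other"


def dipeptide_freq(cds_set, background_set, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Adjacent amino-acid pair frequencies of a set vs a background.

    CDSs are translated (terminal stop dropped); frequencies are over the
    400 possible pairs; enrichment is log2((f_set + pc)/(f_bg + pc)).
    """

    def _pair_freqs(genes) -> pd.Series:
        genes = list(genes.genes) if hasattr(genes, "genes") else list(genes)
        counts: dict[str, int] = {}
        for g in genes:
            _validate_cds(g)
            aa = str(Seq(g.cds_sequence).translate()).rstrip("*")
            for i in range(len(aa) - 1):
                pair = aa[i : i + 2]
                counts[pair] = counts.get(pair, 0) + 1
        s = pd.Series(counts, dtype=float)
        return s / s.sum()

    aas = sorted(set(GENETIC_CODE.values()))
    pairs = pd.Index([a + b for a in aas for b in aas], name="aa_pair")
    f_set = _pair_freqs(cds_set).reindex(pairs, fill_value=0.0)
    f_bg = _pair_freqs(background_set).reindex(pairs, fill_value=0.0)
    return pd.DataFrame({
        "aa_pair": pairs,
        "freq_set": f_set.to_numpy(),
        "freq_background": f_bg.to_numpy(),
        "log2_enrichment": np.log2((f_set + pseudocount) / (f_bg + pseudocount)).to_numpy(),
    })
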