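"""A-site codon occupancy for monosome and disome footprints.

Footprints are size-partitioned into monosome ([25,40) nt) and disome
([40,80] nt) classes, assigned an A-site codon via a length-dependent 5'
offset (for disomes the offset targets the leading ribosome's A site),
and summarized as per-codon occupancies: the mean gene-normalized density
over all occurrences of a codon across sufficiently covered genes, with
the first/last codons excluded to avoid initiation/termination artifacts.
Also provides condition occupancy ratios, meta-codon profiles, per-gene
density tracks, and translation-efficiency (TE) gene sets.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .synthetic import (
    SENSE_CODONS,
    InvalidConfigError,
    OffsetTable,
    Transcriptome,
    default_offsets,
)

logger = logging.getLogger(__name__)

MONO_RANGE = (25, 40)   # [25, 40)
DI_RANGE = (40, 80)     # [40, 80]


def partition_by_size(fp: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split footprints into monosome [25,40) and disome [40,80] classes;
    length 40 is assigned to the disome class.  Others are dropped."""
    lengths = fp["length"]
    mono = fp[(lengths >= MONO_RANGE[0]) & (lengths < MONO_RANGE[1])].copy()
    di = fp[(lengths >= DI_RANGE[0]) & (lengths <= DI_RANGE[1])].copy()
    dropped = len(fp) - len(mono) - len(di)
    if dropped:
        logger.info("partition_by_size: dropped %d out-of-range footprints", dropped)
    mono["library"] = "mono"
    di["library"] = "di"
    return mono, di


def assign_asite(fp: pd.DataFrame, offsets: OffsetTable | None = None,
                 cds_start: int = 0, library: str | None = None) -> pd.Series:
    """A-site codon index (0-based within the CDS) per footprint.

    codon_index = floor((five_prime_pos + offset - cds_start) / 3); NaN when
    no offset is defined for the footprint length (those are skipped and
    counted).
    """
    offsets = offsets or default_offsets()
    if library is None:
        libs = fp["library"]
    else:
        libs = pd.Series(library, index=fp.index)
    off = pd.Series(
        [offsets.offset(l, int(L)) for l, L in zip(libs, fp["length"])],
        index=fp.index, dtype="float64",
    )
    n_missing = int(off.isna().sum())
    if n_missing:
        logger.info("assign_asite: %d footprints with undefined offset skipped", n_missing)
    return np.floor((fp["five_prime_pos"] + off - cds_start) / 3)


def _gene_count_vectors(fp: pd.DataFrame, txome: Transcriptome,
                        offsets: OffsetTable) -> dict[str, np.ndarray]:
    """Per-gene vector of A-site footprint counts per codon position."""
    idx = assign_asite(fp, offsets)
    ok = idx.notna()
    sub = fp[ok]
    idx = idx[ok].astype(int)
    vectors: dict[str, np.ndarray] = {}
    for gid, gidx in idx.groupby(sub["transcript_id"], observed=True):
        if gid not in txome:
            raise KeyError(f"unknown transcript {gid}")
        n = txome[gid].n_codons
        vals = gidx.to_numpy()
        vals = vals[(vals >= 0) & (vals < n)]
        vectors[gid] = np.bincount(vals, minlength=n).astype(float)
    return vectors


def _codon_codes(txome: Transcriptome, gid: str) -> np.ndarray:
    codon_to_i = {c: i for i, c in enumerate(SENSE_CODONS)}
    return np.array([codon_to_i.get(c, -1) for c in txome[gid].codons])


def codon_occupancy(fp: pd.DataFrame, txome: Transcriptome,
                    offsets: OffsetTable | None = None,
                    edge_exclusion: int = 20,
                    min_gene_density: float = 0.5,
                    rescale: bool = True) -> pd.DataFrame:
    """Per-codon A-site occupancy over the 61 sense codons.

    For every gene whose mean count over interior codon positions (excluding
    ``edge_exclusion`` codons at both ends) reaches ``min_gene_density``,
    densities are normalized by that gene mean; occupancy(c) is the mean
    normalized density over all interior occurrences of codon c, with equal
    occurrence weight, finally rescaled so the mean over observed codons is 1.
    """
    offsets = offsets or default_offsets()
    vectors = _gene_count_vectors(fp, txome, offsets)
    sums = np.zeros(len(SENSE_CODONS))
    occ_n = np.zeros(len(SENSE_CODONS))
    n_qualifying = 0
    for gid, counts in vectors.items():
        n = counts.size
        interior = slice(edge_exclusion, n - edge_exclusion)
        inc = counts[interior]
        if inc.size == 0:
            continue
        mean = inc.mean()
        if mean < min_gene_density:
            continue
        n_qualifying += 1
        norm = inc / mean
        codes = _codon_codes(txome, gid)[interior]
        valid = codes >= 0
        np.add.at(sums, codes[valid], norm[valid])
        np.add.at(occ_n, codes[valid], 1)
    if n_qualifying == 0:
        raise InvalidConfigError(
            "no genes pass the minimum density filter "
            f"(min_gene_density={min_gene_density}); increase depth")
    observed = occ_n > 0
    occupancy = np.full(len(SENSE_CODONS), np.nan)
    occupancy[observed] = sums[observed] / occ_n[observed]
    if rescale:
        occupancy[observed] /= occupancy[observed].mean()
    out = pd.DataFrame({
        "codon": SENSE_CODONS,
        "occupancy": occupancy,
        "n_occurrences": occ_n,
    })
    return out[observed].reset_index(drop=True)


def occupancy_ratio(ko: pd.DataFrame, wt: pd.DataFrame) -> pd.DataFrame:
    """Per-codon KO/WT occupancy ratio; codons absent in either table (or
    with zero WT occupancy) are omitted with a log note."""
    merged = ko.merge(wt, on="codon", suffixes=("_ko", "_wt"))
    zero = merged["occupancy_wt"] == 0
    if zero.any():
        logger.info("occupancy_ratio: omitted %d codons with zero WT occupancy",
                    int(zero.sum()))
    merged = merged[~zero].copy()
    merged["ratio_ko_wt"] = merged["occupancy_ko"] / merged["occupancy_wt"]
    return merged[["codon", "occupancy_ko", "occupancy_wt", "ratio_ko_wt"]]


def metacodon(fp: pd.DataFrame, txome: Transcriptome, codon: str,
              offsets: OffsetTable | None = None, window: int = 30,
              edge_exclusion: int = 20,
              min_gene_density: float = 0.5) -> pd.DataFrame:
    """Mean normalized ribosome density at offsets -window..+window codons
    around every occurrence of ``codon`` lying at least ``window`` codons
    from both CDS ends, across qualifying genes."""
    if codon not in SENSE_CODONS:
        raise InvalidConfigError(f"{codon!r} is not a sense codon")
    offsets = offsets or default_offsets()
    vectors = _gene_count_vectors(fp, txome, offsets)
    acc = np.zeros(2 * window + 1)
    n_occ = 0
    for gid, counts in vectors.items():
        n = counts.size
        inc = counts[edge_exclusion : n - edge_exclusion]
        if inc.size == 0 or inc.mean() < min_gene_density:
            continue
        norm_full = counts / inc.mean()
        codes = txome[gid].codons
        for i in range(window, n - window):
            if codes[i] == codon:
                acc += norm_full[i - window : i + window + 1]
                n_occ += 1
    if n_occ == 0:
        warnings.warn(f"metacodon: no interior occurrences of {codon}", stacklevel=2)
        profile = np.full(2 * window + 1, np.nan)
    else:
        profile = acc / n_occ
    return pd.DataFrame({
        "offset": np.arange(-window, window + 1),
        "mean_density": profile,
        "n_occurrences": n_occ,
    })


def gene_profile(fp: pd.DataFrame, txome: Transcriptome, gene_id: str,
                 offsets: OffsetTable | None = None) -> pd.DataFrame:
    """Per-codon A-site footprint counts for one gene, raw and
    gene-mean-normalized (zero vector when the gene has no coverage)."""
    if gene_id not in txome:
        raise KeyError(f"unknown gene {gene_id}")
    offsets = offsets or default_offsets()
    sub = fp[fp["transcript_id"] == gene_id]
    n = txome[gene_id].n_codons
    if len(sub) == 0:
        counts = np.zeros(n)
    else:
        counts = _gene_count_vectors(sub, txome, offsets).get(gene_id, np.zeros(n))
    mean = counts.mean()
    return pd.DataFrame({
        "codon_index": np.arange(n),
        "codon": txome[gene_id].codons,
        "count": counts,
        "normalized": counts / mean if mean > 0 else np.zeros(n),
    })


# ---------------------------------------------------------------------------
# Translation efficiency
# ---------------------------------------------------------------------------

def compute_te(rpf_counts: pd.DataFrame, rna_counts: pd.DataFrame,
               cds_lengths: dict[str, int] | None = None,
               min_counts: float = 32.0,
               down_threshold_log2: float = -0.585,
               up_threshold_log2: float = 0.585) -> tuple[pd.DataFrame, set, set]:
    """Per-gene translation efficiency and delta-TE gene sets.

    te = (RPF count / CDS length) / (RNA count / CDS length) per condition
    (replicates summed); delta_te = log2 te_KO - log2 te_WT.  Genes must
    reach ``min_counts`` in every (library, condition) to be classified;
    genes with zero RNA count are excluded with a log note.  TE-down/up sets
    use the log2 thresholds (defaults +-log2(1.5)).
    """
    cds_lengths = cds_lengths or {}

    def _sum(tbl):
        return tbl.pivot_table(index="gene_id", columns="condition",
                               values="count", aggfunc="sum", fill_value=0)

    rpf = _sum(rpf_counts)
    rna = _sum(rna_counts)
    genes = sorted(set(rpf.index) & set(rna.index))
    rpf = rpf.reindex(genes)
    rna = rna.reindex(genes)
    rows = []
    te_down, te_up = set(), set()
    n_zero_rna = 0
    for g in genes:
        L = cds_lengths.get(g, 1)
        te = {}
        for cond in ("WT", "KO"):
            if cond not in rpf.columns or cond not in rna.columns:
                raise KeyError(f"missing condition {cond} in count tables")
            if rna.loc[g, cond] == 0:
                te[cond] = np.nan
            else:
                te[cond] = (rpf.loc[g, cond] / L) / (rna.loc[g, cond] / L)
            rows.append({"gene_id": g, "condition": cond,
                         "rpf_count": float(rpf.loc[g, cond]),
                         "rna_count": float(rna.loc[g, cond]),
                         "te": te[cond]})
        if np.isnan(te["WT"]) or np.isnan(te["KO"]):
            n_zero_rna += 1
            continue
        min_obs = min(rpf.loc[g, "WT"], rpf.loc[g, "KO"],
                      rna.loc[g, "WT"], rna.loc[g, "KO"])
        if min_obs < min_counts or te["WT"] <= 0 or te["KO"] <= 0:
            continue
        dte = np.log2(te["KO"]) - np.log2(te["WT"])
        if dte <= down_threshold_log2:
            te_down.add(g)
        elif dte >= up_threshold_log2:
            te_up.add(g)
    if n_zero_rna:
        logger.info("compute_te: excluded %d genes with zero RNA counts", n_zero_rna)
    table = pd.DataFrame(rows)
    piv = table.pivot_table(index="gene_id", columns="condition", values="te")
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.log2(piv.get("KO")) - np.log2(piv.get("WT"))
    table = table.merge(delta.rename("delta_te_log2"), left_on="gene_id",
                        right_index=True, how="left")
    return table, te_down, te_up
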