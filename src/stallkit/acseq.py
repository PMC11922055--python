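"""Chemical-probing (ac4C-seq style) misincorporation and RT-stop analysis.

Reduced-vs-mock read sets are preprocessed (adapter trim, UMI-aware
deduplication), exhaustively ungapped-aligned against the tRNA reference,
piled up per position, and cytidine sites are called from the net C->T
misincorporation rate with depth and stoichiometry filters plus the
5'-CCG-3' consensus annotation and knockout-sensitivity classification.

Coordinates are 0-based half-open internally; TSV reports add a 1-based
position column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import (
    InvalidConfigError,
    Read,
    ReadSet,
    TRNAReference,
    encode_bases,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Read preprocessing
# ---------------------------------------------------------------------------

def _mismatches_leq(a: str, b: str, limit: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def trim_adapter(seq: str, adapter: str, min_overlap: int = 10,
                 max_mismatch: int = 1) -> str:
    """Remove a 3' adapter: a read suffix matching an adapter prefix with
    >= ``min_overlap`` nt and <= ``max_mismatch`` mismatches is trimmed
    (longest qualifying overlap wins)."""
    if seq.endswith(adapter):  # fast path: complete adapter
        return seq[: -len(adapter)]
    for o in range(min(len(adapter), len(seq)), min_overlap - 1, -1):
        if _mismatches_leq(seq[-o:], adapter[:o], max_mismatch):
            return seq[:-o]
    return seq


def preprocess_reads(raw: ReadSet, adapter: str, umi_5p_len: int = 0,
                     umi_3p_len: int = 0) -> ReadSet:
    """Adapter-trim, deduplicate (on the full sequence INCLUDING UMI bases,
    first occurrence kept), then strip UMI bases."""
    if len(adapter) < 10:
        raise InvalidConfigError("adapter must be at least 10 nt")
    if umi_5p_len < 0 or umi_3p_len < 0:
        raise InvalidConfigError("UMI lengths must be >= 0")
    seen: set[str] = set()
    out: list[Read] = []
    for r in raw:
        seq = trim_adapter(r.sequence, adapter)
        if seq in seen:
            continue
        seen.add(seq)
        insert = seq[umi_5p_len : len(seq) - umi_3p_len if umi_3p_len else None]
        if insert:
            out.append(Read(r.read_id, insert))
    return ReadSet(out)


# ---------------------------------------------------------------------------
# Ungapped alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int  # exclusive
    mismatch_positions: tuple[int, ...]
    multimap_count: int = 1

    @property
    def weight(self) -> float:
        return 1.0 / self.multimap_count


@dataclass
class AlignmentSet:
    alignments: list[Alignment] = field(default_factory=list)
    n_unaligned: int = 0
    #: read_id -> aligned (insert) sequence, for pileup construction
    sequences: dict[str, str] = field(default_factory=dict)

    def __len__(self):
        return len(self.alignments)

    def __iter__(self):
        return iter(self.alignments)


def align_ungapped(reads: ReadSet, ref: TRNAReference,
                   max_mismatch_frac: float = 0.1) -> AlignmentSet:
    """Exhaustive ungapped scan of every read over all references/offsets.

    All placements achieving the minimum mismatch count are kept when that
    count is within ``max_mismatch_frac`` of the read length; multimapping
    reads receive fractional weight 1/multimap_count.  Unaligned reads are
    dropped and counted.
    """
    if len(ref) == 0:
        raise InvalidConfigError("reference is empty")
    ref_codes = {g.gene_id: encode_bases(g.sequence) for g in ref.genes}

    # group identical sequences; align each unique sequence once
    groups: dict[str, list[str]] = {}
    for r in reads:
        groups.setdefault(r.sequence, []).append(r.read_id)

    result = AlignmentSet()
    # cache sliding windows per (gene, read_len)
    window_cache: dict[tuple[str, int], np.ndarray] = {}
    for seq, read_ids in groups.items():
        L = len(seq)
        if L == 0:
            result.n_unaligned += len(read_ids)
            continue
        q = encode_bases(seq)
        best = None  # (mismatches, [(gene_id, offset)])
        for g in ref.genes:
            rc = ref_codes[g.gene_id]
            if len(rc) < L:
                continue
            key = (g.gene_id, L)
            win = window_cache.get(key)
            if win is None:
                win = np.lib.stride_tricks.sliding_window_view(rc, L)
                window_cache[key] = win
            mm = (win != q).sum(axis=1)
            gmin = int(mm.min())
            if best is None or gmin < best[0]:
                best = (gmin, [(g.gene_id, int(o)) for o in np.nonzero(mm == gmin)[0]])
            elif gmin == best[0]:
                best[1].extend((g.gene_id, int(o)) for o in np.nonzero(mm == gmin)[0])
        if best is None or best[0] > max_mismatch_frac * L:
            result.n_unaligned += len(read_ids)
            continue
        n_placements = len(best[1])
        placements = []
        for gene_id, off in best[1]:
            rc = ref_codes[gene_id]
            mpos = tuple(int(p) for p in np.nonzero(rc[off : off + L] != q)[0] + off)
            placements.append((gene_id, off, mpos))
        for rid in read_ids:
            result.sequences[rid] = seq
            for gene_id, off, mpos in placements:
                result.alignments.append(
                    Alignment(rid, gene_id, off, off + L, mpos, n_placements)
                )
    if result.n_unaligned:
        logger.info("align_ungapped: dropped %d unaligned reads", result.n_unaligned)
    return result


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

@dataclass
class Pileup:
    """Weighted per-position base counts (rows A,C,G,T) and RT-stop counts
    for one reference gene.  Counts are kept in full (real) precision."""

    counts: np.ndarray  # (4, L) float
    stop: np.ndarray    # (L,) float

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class PileupTable:
    tables: dict[str, Pileup]

    def __getitem__(self, ref_id: str) -> Pileup:
        return self.tables[ref_id]

    def __contains__(self, ref_id):
        return ref_id in self.tables

    def __iter__(self):
        return iter(self.tables)


def build_pileup(alns: AlignmentSet, reads: ReadSet | None, ref: TRNAReference) -> PileupTable:
    """Accumulate weighted base counts per covered position and RT-stop
    counts (an alignment beginning at position s>0 contributes a stop at
    s-1, i.e. the cDNA terminated one nucleotide 3' of that position)."""
    seqs = dict(alns.sequences)
    if reads is not None:
        for r in reads:
            seqs.setdefault(r.read_id, r.sequence)
    tables = {g.gene_id: Pileup(np.zeros((4, len(g.sequence))), np.zeros(len(g.sequence)))
              for g in ref.genes}
    # group alignments sharing (ref, start, sequence, weight) to vectorize
    grouped: dict[tuple[str, int, str], float] = {}
    for a in alns:
        if a.ref_id not in tables:
            raise KeyError(f"alignment references unknown gene {a.ref_id}")
        pl = tables[a.ref_id]
        if a.ref_start < 0 or a.ref_end > pl.counts.shape[1]:
            raise ValueError(f"alignment outside reference bounds for {a.ref_id}")
        seq = seqs[a.read_id]
        key = (a.ref_id, a.ref_start, seq)
        grouped[key] = grouped.get(key, 0.0) + a.weight
    for (ref_id, start, seq), w in grouped.items():
        pl = tables[ref_id]
        codes = encode_bases(seq)
        pl.counts[codes, np.arange(start, start + len(codes))] += w
        if start > 0:
            pl.stop[start - 1] += w
    return PileupTable(tables)


# ---------------------------------------------------------------------------
# Site calling
# ---------------------------------------------------------------------------

def _ct_rate(pl: Pileup, pos: int) -> float:
    c = pl.counts[1, pos]
    t = pl.counts[3, pos]
    return float(t / (c + t)) if (c + t) > 0 else 0.0


def call_sites(reduced: PileupTable, mock: PileupTable, ref: TRNAReference,
               min_depth: float = 100.0, min_net_rate: float = 0.02) -> pd.DataFrame:
    """Call cytidine modification sites from reduced-vs-mock pileups.

    For every reference C position with reduced-library coverage the C->T
    misincorporation rate T/(C+T) is computed in each library (A/G reads at
    C positions are tracked in the pileup but excluded from the rate); the
    net rate is the mock-subtracted difference floored at 0.  A site passes
    when reduced depth is strictly greater than ``min_depth`` and the net
    rate is at least ``min_net_rate``.  ``is_ccg`` flags the 5'-CCG-3'
    consensus around the position.
    """
    rows = []
    for g in ref.genes:
        if g.gene_id not in reduced.tables or g.gene_id not in mock.tables:
            raise KeyError(f"pileups missing gene {g.gene_id}")
        red = reduced[g.gene_id]
        mk = mock[g.gene_id]
        if red.counts.shape != mk.counts.shape:
            raise ValueError(f"mismatched references for {g.gene_id}")
        depth_red = red.depth
        depth_mock = mk.depth
        stop = red.stop
        for pos, base in enumerate(g.sequence):
            if base != "C" or depth_red[pos] <= 0:
                continue
            rate_red = _ct_rate(red, pos)
            rate_mock = _ct_rate(mk, pos)
            net = max(rate_red - rate_mock, 0.0)
            sf = stop[pos] / (stop[pos] + depth_red[pos]) if (stop[pos] + depth_red[pos]) > 0 else 0.0
            is_ccg = g.sequence[max(pos - 1, 0) : pos + 2] == "CCG" and pos >= 1
            rows.append({
                "ref_id": g.gene_id,
                "pos": pos,
                "rate_reduced": rate_red,
                "rate_mock": rate_mock,
                "net_rate": net,
                "depth_reduced": float(depth_red[pos]),
                "depth_mock": float(depth_mock[pos]),
                "stop_fraction": float(sf),
                "is_ccg": bool(is_ccg),
                "passes": bool(depth_red[pos] > min_depth and net >= min_net_rate),
            })
    return pd.DataFrame(rows, columns=[
        "ref_id", "pos", "rate_reduced", "rate_mock", "net_rate",
        "depth_reduced", "depth_mock", "stop_fraction", "is_ccg", "passes",
    ])


def stop_profile(pileup: PileupTable) -> pd.DataFrame:
    """Per-position RT-stop fraction: stop/(stop + readthrough depth)."""
    if not pileup.tables:
        raise InvalidConfigError("pileup table is empty")
    rows = []
    for ref_id, pl in pileup.tables.items():
        depth = pl.depth
        for pos in range(pl.counts.shape[1]):
            tot = pl.stop[pos] + depth[pos]
            rows.append({
                "ref_id": ref_id,
                "pos": pos,
                "stop_count": float(pl.stop[pos]),
                "depth": float(depth[pos]),
                "stop_fraction": float(pl.stop[pos] / tot) if tot > 0 else 0.0,
            })
    return pd.DataFrame(rows)


def thumpd1_sensitivity(sites_wt: pd.DataFrame, sites_ko: pd.DataFrame,
                        ko_max_net: float = 0.02) -> pd.DataFrame:
    """Classify WT-passing sites as knockout-sensitive when their net
    misincorporation collapses below ``ko_max_net`` in the KO comparison.
    Positions present in only one table are reported uncallable (NA)."""
    merged = sites_wt.merge(
        sites_ko[["ref_id", "pos", "net_rate"]].rename(columns={"net_rate": "net_rate_ko"}),
        on=["ref_id", "pos"], how="outer", indicator=True,
    )
    sensitive = pd.array([pd.NA] * len(merged), dtype="boolean")
    callable_mask = (merged["_merge"] == "both").to_numpy()
    sensitive[callable_mask] = (
        merged.loc[callable_mask, "passes"].astype(bool)
        & (merged.loc[callable_mask, "net_rate_ko"] < ko_max_net)
    ).to_numpy()
    merged["thumpd1_sensitive"] = sensitive
    return merged.drop(columns="_merge")


def write_sites_tsv(sites: pd.DataFrame, path) -> None:
    """Write a site report with 1-based inclusive positions."""
    out = sites.copy()
    out.insert(2, "pos_1based", out["pos"] + 1)
    out.to_csv(path, sep="\t", index=False)
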