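"""Synthetic data generators emulating the study's data-generating processes.

Every downstream stage of the pipeline (chemical-probing site calling,
isodecoder quantification, ribosome/disome occupancy, assay arithmetic)
is driven by reads and tables produced here, so the generators encode the
statistical structure those analyses assume:

* borohydride-reduction chemistry at acetylated C12 with a stop-versus-
  readthrough branch and per-base background error,
* condition-specific isodecoder abundance shifts (the knockout depletion
  profile),
* codon-specific ribosome dwell times for monosome and stacked-disome
  footprints,
* periodate-protected qPCR of charged tRNA,
* dihybrid-cross offspring with genotype-specific viability.

All generators draw from a single ``numpy.random.Generator`` seeded per
call; fixed (config, seed) pairs are byte-reproducible.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = np.array(["A", "C", "G", "T"])
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: 3' sequencing adapter appended to simulated chemical-probing reads.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

# Anticodons (DNA alphabet) and isodecoder copy numbers for the substrate
# complement: 26 Ser/Leu genes spanning 9 distinct anticodons.  Copy counts
# include every isodecoder named in the knockout depletion profile.
SUBSTRATE_ANTICODONS: dict[tuple[str, str], int] = {
    ("Leu", "AAG"): 3,
    ("Leu", "CAA"): 3,
    ("Leu", "CAG"): 2,
    ("Leu", "TAA"): 3,
    ("Leu", "TAG"): 2,
    ("Ser", "AGA"): 3,
    ("Ser", "CGA"): 3,
    ("Ser", "GCT"): 3,
    ("Ser", "TGA"): 4,
}

#: Fold-depletions applied to the KO tRNA abundance profile.
KO_DEPLETION: dict[str, float] = {
    "Leu-UAA-2": 4.0,
    "Ser-AGA-3": 1.5,
    "Ser-UGA-4": 1.5,
    "Leu-AAG-3": 1.5,
    "Leu-UAA-3": 1.5,
}

#: Codons with doubled dwell weight in the KO monosome model (A-site stalls).
KO_MONO_STALL_CODONS = ("TTG", "CTA", "CTT", "TTA")
#: Codons with doubled dwell weight in the KO disome model (collisions).
KO_DI_STALL_CODONS = ("TCA", "CTC", "TTG", "TTA")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in STOP_CODONS
)


class InvalidConfigError(ValueError):
    """Raised when generator parameters are inconsistent or empty."""


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def dna_to_rna_display(anticodon: str) -> str:
    """DNA-stored anticodon rendered RNA-style for gene ids (TAA -> UAA)."""
    return anticodon.replace("T", "U")


# ---------------------------------------------------------------------------
# tRNA reference
# ---------------------------------------------------------------------------

@dataclass
class TRNAGene:
    gene_id: str
    amino_acid: str
    anticodon: str  # DNA alphabet
    copy_index: int
    sequence: str
    c12_index: int | None = None
    is_substrate: bool = False


@dataclass
class TRNAReference:
    """Isodecoder gene set: the substrate universe for acetylation calling."""

    genes: list[TRNAGene]

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise InvalidConfigError("duplicate gene_id in reference")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self):
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> TRNAGene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def substrates(self) -> list[TRNAGene]:
        return [g for g in self.genes if g.is_substrate]

    def to_fasta(self, handle_or_path) -> None:
        records = []
        for g in self.genes:
            desc = (
                f"amino_acid={g.amino_acid} anticodon={g.anticodon} "
                f"copy_index={g.copy_index} is_substrate={int(g.is_substrate)}"
            )
            if g.c12_index is not None:
                desc += f" c12_index={g.c12_index}"
            records.append(SeqRecord(Seq(g.sequence), id=g.gene_id, description=desc))
        SeqIO.write(records, handle_or_path, "fasta")

    @classmethod
    def from_fasta(cls, handle_or_path) -> "TRNAReference":
        genes = []
        for rec in SeqIO.parse(handle_or_path, "fasta"):
            meta = {}
            for token in rec.description.split()[1:]:
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            parts = rec.id.split("-")
            genes.append(
                TRNAGene(
                    gene_id=rec.id,
                    amino_acid=meta.get("amino_acid", parts[0]),
                    anticodon=meta.get("anticodon", parts[1].replace("U", "T") if len(parts) > 1 else ""),
                    copy_index=int(meta.get("copy_index", parts[-1] if parts[-1].isdigit() else 1)),
                    sequence=str(rec.seq),
                    c12_index=int(meta["c12_index"]) if "c12_index" in meta else None,
                    is_substrate=bool(int(meta.get("is_substrate", 0))),
                )
            )
        return cls(genes)

    def fasta_bytes(self) -> bytes:
        buf = io.StringIO()
        self.to_fasta(buf)
        return buf.getvalue().encode()


def make_trna_reference(
    substrate_copies: dict[tuple[str, str], int] | None = None,
    n_decoys: int = 0,
    length_range: tuple[int, int] = (74, 79),
    c12_index: int = 11,
    seed: int | None = 0,
) -> TRNAReference:
    """Generate an isodecoder reference.

    Substrate genes are Ser/Leu isodecoders carrying the 5'-CCG-3' consensus
    centred on the annotated C12 (0-based ``c12_index``); decoys are random
    tRNA-like sequences with no annotated modification site.  The default
    substrate complement is 26 genes over 9 anticodons.
    """
    if substrate_copies is None:
        substrate_copies = SUBSTRATE_ANTICODONS
    total_sub = sum(substrate_copies.values()) if substrate_copies else 0
    if total_sub < 0 or any(v < 0 for v in substrate_copies.values()):
        raise InvalidConfigError("substrate copy counts must be >= 0")
    if total_sub + n_decoys == 0:
        raise InvalidConfigError("reference must contain at least one gene")

    rng = _rng(seed)
    genes: list[TRNAGene] = []
    for (aa, anticodon), copies in sorted(substrate_copies.items()):
        for copy_index in range(1, copies + 1):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = list(_random_seq(rng, length))
            seq[c12_index - 1 : c12_index + 2] = list("CCG")
            # place the anticodon in the anticodon-loop region for realism
            ac_pos = 33
            seq[ac_pos : ac_pos + 3] = list(anticodon)
            gene_id = f"{aa}-{dna_to_rna_display(anticodon)}-{copy_index}"
            genes.append(
                TRNAGene(
                    gene_id=gene_id,
                    amino_acid=aa,
                    anticodon=anticodon,
                    copy_index=copy_index,
                    sequence="".join(seq),
                    c12_index=c12_index,
                    is_substrate=True,
                )
            )
    decoy_aas = ["Ala", "Gly", "Val", "Thr", "Pro", "Lys", "Arg", "Asp", "Glu", "Phe"]
    for k in range(1, n_decoys + 1):
        aa = decoy_aas[(k - 1) % len(decoy_aas)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _random_seq(rng, length)
        anticodon = seq[33:36]
        genes.append(
            TRNAGene(
                gene_id=f"{aa}-{dna_to_rna_display(anticodon)}-decoy{k}",
                amino_acid=aa,
                anticodon=anticodon,
                copy_index=k,
                sequence=seq,
                c12_index=None,
                is_substrate=False,
            )
        )
    return TRNAReference(genes)


# ---------------------------------------------------------------------------
# Acetylation profile and reduction chemistry
# ---------------------------------------------------------------------------

@dataclass
class AcetylationProfile:
    """Per-gene acetylation stoichiometry and reduction chemistry.

    ``p_mis`` and ``p_stop`` are the probabilities, conditional on a molecule
    being acetylated and chemically reduced, of reading C->T at C12 or of the
    reverse transcriptase stopping adjacent to C12.  ``epsilon`` is the
    per-base background error rate applied everywhere in all reads.
    """

    stoichiometry: dict[str, float]
    p_mis: dict[str, float]
    p_stop: dict[str, float]
    epsilon: float = 0.002

    def __post_init__(self):
        for gid in self.stoichiometry:
            pm = self.p_mis.get(gid, 0.0)
            ps = self.p_stop.get(gid, 0.0)
            if pm + ps > 1 + 1e-12:
                raise InvalidConfigError(f"p_mis + p_stop > 1 for {gid}")
        if not (0 <= self.epsilon <= 0.02):
            raise InvalidConfigError("epsilon must be in [0, 0.02]")

    @classmethod
    def default(cls, ref: TRNAReference, stoichiometry: float = 0.9,
                epsilon: float = 0.002, knockout: bool = False) -> "AcetylationProfile":
        """Default chemistry: Leu substrates stop-prone (p_mis=0.35,
        p_stop=0.35), Ser substrates misincorporation-penetrant (p_mis=0.6,
        p_stop=0.1).  ``knockout=True`` zeroes all stoichiometries."""
        s, pm, ps = {}, {}, {}
        for g in ref.genes:
            if g.is_substrate:
                s[g.gene_id] = 0.0 if knockout else stoichiometry
                if g.amino_acid == "Leu":
                    pm[g.gene_id], ps[g.gene_id] = 0.35, 0.35
                else:
                    pm[g.gene_id], ps[g.gene_id] = 0.6, 0.1
            else:
                s[g.gene_id] = 0.0
                pm[g.gene_id], ps[g.gene_id] = 0.0, 0.0
        return cls(stoichiometry=s, p_mis=pm, p_stop=ps, epsilon=epsilon)


@dataclass
class Read:
    read_id: str
    sequence: str


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)

    def __len__(self):
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def to_fastq(self, handle_or_path) -> None:
        close = False
        if isinstance(handle_or_path, (str,)):
            handle = open(handle_or_path, "w")
            close = True
        else:
            handle = handle_or_path
        try:
            for r in self.reads:
                handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
        finally:
            if close:
                handle.close()

    @classmethod
    def from_fastq(cls, handle_or_path) -> "ReadSet":
        reads = [Read(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle_or_path, "fastq")]
        return cls(reads)


def _apply_errors(rng: np.random.Generator, seq_codes: np.ndarray, epsilon: float) -> np.ndarray:
    """Substitute each base independently with probability epsilon."""
    if epsilon <= 0:
        return seq_codes
    hits = rng.random(seq_codes.shape) < epsilon
    if not hits.any():
        return seq_codes
    out = seq_codes.copy()
    # draw a uniformly random *different* base: add 1..3 mod 4
    out[hits] = (out[hits] + rng.integers(1, 4, size=int(hits.sum()))) % 4
    return out


_CODE_OF = np.zeros(256, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE_OF[ord(_b)] = _i


def encode_bases(seq: str) -> np.ndarray:
    """DNA string -> int codes (A=0, C=1, G=2, T=3)."""
    return _CODE_OF[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int8)


def decode_bases(codes: np.ndarray) -> str:
    return "".join(BASES[codes])


def simulate_ac4cseq_reads(
    ref: TRNAReference,
    profile: AcetylationProfile,
    treatment: str,
    depth: int,
    seed: int | None = 0,
    adapter: str | None = None,
    umi_5p_len: int = 0,
    umi_3p_len: int = 0,
) -> ReadSet:
    """Simulate reduced- or mock-treatment chemical-probing reads.

    Under ``reduced``, each molecule of a substrate gene is acetylated with
    probability ``stoichiometry``; an acetylated, reduced molecule either
    truncates (RT stop; the read's 5'-most covered position is c12_index+1,
    probability ``p_stop``), carries T at C12 (probability ``p_mis``), or
    reads through as C.  Under ``mock``, only background errors occur.
    Background errors apply independently at every position of every read.

    If ``adapter``/UMI lengths are given, reads are emitted as
    5'UMI + insert + 3'UMI + adapter, ready for ``acseq.preprocess_reads``.
    """
    if treatment not in ("reduced", "mock"):
        raise ValueError(f"treatment must be 'reduced' or 'mock', got {treatment!r}")
    if depth < 1:
        raise InvalidConfigError("depth must be >= 1")
    rng = _rng(seed)
    reads: list[Read] = []
    for g in ref.genes:
        full = encode_bases(g.sequence)
        s = profile.stoichiometry.get(g.gene_id, 0.0)
        pm = profile.p_mis.get(g.gene_id, 0.0)
        ps = profile.p_stop.get(g.gene_id, 0.0)
        n = depth
        # branch per molecule: 0 = readthrough C, 1 = misincorporation T, 2 = stop
        if treatment == "reduced" and s > 0 and g.c12_index is not None:
            u = rng.random(n)
            acety = u < s
            v = rng.random(n)
            branch = np.zeros(n, dtype=np.int8)
            branch[acety & (v < ps)] = 2
            branch[acety & (v >= ps) & (v < ps + pm)] = 1
        else:
            branch = np.zeros(n, dtype=np.int8)
        for i in range(n):
            if branch[i] == 2:
                insert = full[g.c12_index + 1 :]
            else:
                insert = full.copy()
                if branch[i] == 1:
                    insert[g.c12_index] = BASE_INDEX["T"]
            insert = _apply_errors(rng, insert, profile.epsilon)
            seq = decode_bases(insert)
            if umi_5p_len or umi_3p_len or adapter:
                umi5 = _random_seq(rng, umi_5p_len)
                umi3 = _random_seq(rng, umi_3p_len)
                seq = umi5 + seq + umi3 + (adapter or "")
            reads.append(Read(f"{g.gene_id}|{treatment}|{i}", seq))
    return ReadSet(reads)


# ---------------------------------------------------------------------------
# tRNA-seq reads
# ---------------------------------------------------------------------------

def default_abundance(ref: TRNAReference, condition: str = "WT") -> dict[str, float]:
    """Relative abundance profile: uniform in WT; in KO the acetylation-
    dependent isodecoders are depleted (Leu-UAA-2 by 4-fold, four others by
    1.5-fold)."""
    ab = {g.gene_id: 1.0 for g in ref.genes}
    if condition == "KO":
        for gid, fold in KO_DEPLETION.items():
            if gid in ab:
                ab[gid] /= fold
    return ab


def default_misinc_signature(ref: TRNAReference, condition: str = "WT",
                             rate: float = 0.3) -> dict[str, dict[int, float]]:
    """Modification-induced mismatch signature tolerated by quantification:
    substrate C12 positions mismatch at ``rate`` when the modification is
    present (WT), and not at all in the KO."""
    if condition == "KO":
        return {}
    return {
        g.gene_id: {g.c12_index: rate}
        for g in ref.genes
        if g.is_substrate and g.c12_index is not None
    }


def simulate_trnaseq_reads(
    ref: TRNAReference,
    abundance: dict[str, float],
    misinc_signature: dict[str, dict[int, float]] | None = None,
    depth: int = 10000,
    seed: int | None = 0,
    background_error: float = 0.001,
) -> ReadSet:
    """Full-length tRNA-seq-style reads sampled proportionally to abundance,
    with modification-induced mismatches injected at annotated positions."""
    gene_ids = [gid for gid in abundance if gid in ref]
    if len(gene_ids) != len(abundance):
        missing = set(abundance) - set(gene_ids)
        raise KeyError(f"abundance names unknown genes: {sorted(missing)}")
    weights = np.array([abundance[g] for g in gene_ids], dtype=float)
    if (weights < 0).any():
        raise InvalidConfigError("abundances must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise InvalidConfigError("at least one abundance must be positive")
    misinc_signature = misinc_signature or {}
    rng = _rng(seed)
    counts = rng.multinomial(depth, weights / total)
    reads: list[Read] = []
    for gid, n in zip(gene_ids, counts):
        if n == 0:
            continue
        gene = ref[gid]
        base = encode_bases(gene.sequence)
        sig = misinc_signature.get(gid, {})
        for i in range(n):
            seq = base.copy()
            for pos, rate in sig.items():
                if rng.random() < rate:
                    # mutate to a random different base (mimics RT mis-read)
                    seq[pos] = (seq[pos] + rng.integers(1, 4)) % 4
            seq = _apply_errors(rng, seq, background_error)
            reads.append(Read(f"{gid}|{i}", decode_bases(seq)))
    return ReadSet(reads)


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

@dataclass
class TranscriptGene:
    gene_id: str
    cds_sequence: str

    @property
    def codons(self) -> list[str]:
        s = self.cds_sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3


@dataclass
class Transcriptome:
    genes: list[TranscriptGene]

    def __post_init__(self):
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self):
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> TranscriptGene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id):
        return gene_id in self._by_id

    @property
    def gene_ids(self):
        return [g.gene_id for g in self.genes]

    def to_fasta(self, handle_or_path) -> None:
        records = [SeqRecord(Seq(g.cds_sequence), id=g.gene_id, description="")
                   for g in self.genes]
        SeqIO.write(records, handle_or_path, "fasta")

    @classmethod
    def from_fasta(cls, handle_or_path) -> "Transcriptome":
        return cls([TranscriptGene(rec.id, str(rec.seq))
                    for rec in SeqIO.parse(handle_or_path, "fasta")])


def make_transcriptome(
    n_genes: int = 50,
    n_codons_range: tuple[int, int] = (150, 300),
    codon_weights: dict[str, float] | None = None,
    embedded_runs: dict[str, tuple[int, list[str]]] | None = None,
    seed: int | None = 0,
) -> Transcriptome:
    """Random CDS set: ATG start, sense-codon body, single terminal stop.

    ``codon_weights`` sets the sampling weights over the 61 sense codons
    (default uniform); positive weight on a stop codon is an error.
    ``embedded_runs`` maps gene_id -> (codon_position, [codons]) to plant
    deterministic codon runs (e.g. a 3xUUA stall reporter).
    """
    if n_genes < 1:
        raise InvalidConfigError("n_genes must be >= 1")
    if codon_weights is None:
        codon_weights = {c: 1.0 for c in SENSE_CODONS}
    for c, w in codon_weights.items():
        if c in STOP_CODONS and w > 0:
            raise InvalidConfigError(f"stop codon {c} has positive coding weight")
    codons = [c for c in SENSE_CODONS if codon_weights.get(c, 0.0) > 0]
    w = np.array([codon_weights[c] for c in codons], dtype=float)
    w /= w.sum()
    rng = _rng(seed)
    genes = []
    embedded_runs = embedded_runs or {}
    for k in range(n_genes):
        gid = f"gene{k + 1:04d}"
        n_codons = int(rng.integers(n_codons_range[0], n_codons_range[1] + 1))
        body = list(np.array(codons)[rng.choice(len(codons), size=n_codons - 2, p=w)])
        seq_codons = ["ATG"] + body + ["TAA"]
        if gid in embedded_runs:
            pos, run = embedded_runs[gid]
            if pos < 1 or pos + len(run) > n_codons - 1:
                raise InvalidConfigError(f"embedded run out of range for {gid}")
            for j, c in enumerate(run):
                if c in STOP_CODONS:
                    raise InvalidConfigError("embedded run contains a stop codon")
                seq_codons[pos + j] = c
        genes.append(TranscriptGene(gid, "".join(seq_codons)))
    return Transcriptome(genes)


# ---------------------------------------------------------------------------
# Dwell model and footprints
# ---------------------------------------------------------------------------

def _triangle_dist(lo: int, hi: int, peak_lo: int, peak_hi: int) -> dict[int, float]:
    lengths = range(lo, hi + 1)
    w = {}
    for L in lengths:
        if peak_lo <= L <= peak_hi:
            w[L] = 4.0
        else:
            w[L] = 1.0 / (1 + min(abs(L - peak_lo), abs(L - peak_hi)))
    total = sum(w.values())
    return {L: v / total for L, v in w.items()}


@dataclass
class OffsetTable:
    """Length -> distance (nt) from footprint 5' end to the first nucleotide
    of the A-site codon, per library.  For disomes the offset targets the
    leading ribosome's A site (trailing ribosome spans the 5' ~30 nt)."""

    mono: dict[int, int]
    di: dict[int, int]

    def offset(self, library: str, length: int) -> int | None:
        table = self.mono if library == "mono" else self.di
        return table.get(length)


def default_offsets() -> OffsetTable:
    mono = {L: (15 if L <= 31 else 16) for L in range(25, 40)}
    di = {L: (45 if L <= 61 else 46) for L in range(46, 81)}
    return OffsetTable(mono=mono, di=di)


@dataclass
class DwellModel:
    """Per-codon ribosome dwell weights and footprint-length distributions.

    Weights are strictly positive and normalized at construction so their
    mean over the 61 sense codons is 1; occupancy estimates downstream are
    therefore directly comparable with the injected weights.
    """

    weights: dict[str, float]
    mono_length_dist: dict[int, float] = field(default_factory=lambda: _triangle_dist(25, 39, 28, 31))
    di_length_dist: dict[int, float] = field(default_factory=lambda: _triangle_dist(50, 70, 58, 62))
    disome_fraction: float = 0.1

    def __post_init__(self):
        missing = set(SENSE_CODONS) - set(self.weights)
        for c in missing:
            self.weights[c] = 1.0
        if any(v <= 0 for v in self.weights.values()):
            raise InvalidConfigError("dwell weights must be strictly positive")
        mean = sum(self.weights[c] for c in SENSE_CODONS) / len(SENSE_CODONS)
        self.weights = {c: self.weights[c] / mean for c in self.weights}
        if not (0 <= self.disome_fraction <= 1):
            raise InvalidConfigError("disome_fraction must be in [0,1]")

    @classmethod
    def flat(cls, **kw) -> "DwellModel":
        return cls(weights={c: 1.0 for c in SENSE_CODONS}, **kw)

    @classmethod
    def default(cls, condition: str, library: str = "mono", **kw) -> "DwellModel":
        """WT: flat dwell.  KO: dwell doubled at the stalling codons
        (monosome: UUG/CUA/CUU/UUA; disome: UCA/CUC/UUG/UUA)."""
        w = {c: 1.0 for c in SENSE_CODONS}
        if condition == "KO":
            stall = KO_MONO_STALL_CODONS if library == "mono" else KO_DI_STALL_CODONS
            for c in stall:
                w[c] = 2.0
        return cls(weights=w, **kw)


def simulate_footprints(
    txome: Transcriptome,
    expression: dict[str, float] | None,
    dwell: DwellModel,
    library: str,
    condition: str,
    depth: int,
    seed: int | None = 0,
    offsets: OffsetTable | None = None,
    edge_codons: int = 20,
    replicate: int = 1,
) -> pd.DataFrame:
    """Sample ribosome footprints with A sites placed codon-proportionally
    to the dwell weights.

    Returns a FootprintSet DataFrame with columns transcript_id,
    five_prime_pos (0-based), length, library, condition, replicate.
    The A-site codon is sampled within each gene's interior (excluding
    ``edge_codons`` at both ends) with probability proportional to the dwell
    weight of the codon at that position; the 5' end is then placed using
    the shared offset convention, so analyzer and simulator agree exactly.
    For disome footprints the sampled codon is the leading ribosome's A site.
    """
    if library not in ("mono", "di"):
        raise ValueError(f"library must be 'mono' or 'di', got {library!r}")
    if depth < 1:
        raise InvalidConfigError("depth must be >= 1")
    offsets = offsets or default_offsets()
    rng = _rng(seed)
    if expression is None:
        expression = {g.gene_id: 1.0 for g in txome.genes}
    gene_ids = list(expression)
    gw = np.array([expression[g] for g in gene_ids], dtype=float)
    if (gw < 0).any() or gw.sum() <= 0:
        raise InvalidConfigError("expression weights must be nonnegative, not all zero")
    ldist = dwell.mono_length_dist if library == "mono" else dwell.di_length_dist
    lengths_sup = np.array(sorted(ldist))
    lprobs = np.array([ldist[L] for L in lengths_sup], dtype=float)
    lprobs /= lprobs.sum()

    per_gene = rng.multinomial(depth, gw / gw.sum())
    frames = []
    for gid, n in zip(gene_ids, per_gene):
        if n == 0:
            continue
        gene = txome[gid]
        codons = gene.codons
        interior = np.arange(edge_codons, gene.n_codons - edge_codons)
        if interior.size == 0:
            raise InvalidConfigError(f"gene {gid} too short for edge exclusion")
        pw = np.array([dwell.weights[codons[i]] for i in interior], dtype=float)
        pw /= pw.sum()
        pos = interior[rng.choice(interior.size, size=n, p=pw)]
        lens = lengths_sup[rng.choice(lengths_sup.size, size=n, p=lprobs)]
        offs = np.array([offsets.offset(library, int(L)) for L in lens])
        five_prime = 3 * pos - offs
        frames.append(pd.DataFrame({
            "transcript_id": gid,
            "five_prime_pos": five_prime,
            "length": lens,
            "library": library,
            "condition": condition,
            "replicate": replicate,
        }))
    fp = pd.concat(frames, ignore_index=True)
    # guard: footprints must lie within the transcript
    lens_by_gene = {g.gene_id: len(g.cds_sequence) for g in txome.genes}
    tlen = fp["transcript_id"].map(lens_by_gene)
    ok = (fp["five_prime_pos"] >= 0) & (fp["five_prime_pos"] + fp["length"] <= tlen)
    return fp[ok].reset_index(drop=True)


def simulate_expression_tables(
    txome: Transcriptome,
    te_effects: dict[str, float] | None = None,
    seed: int | None = 0,
    n_replicates: int = 2,
    mean_rna: float = 500.0,
    mean_rpf: float = 500.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired RNA-seq and ribosome-footprint count tables for WT and KO.

    RNA counts are condition-independent in expectation; KO footprint counts
    are scaled by the per-gene translation-efficiency multiplier.
    """
    te_effects = te_effects or {}
    if any(m <= 0 for m in te_effects.values()):
        raise InvalidConfigError("TE multipliers must be > 0")
    if mean_rna <= 0 or mean_rpf <= 0:
        raise InvalidConfigError("mean counts must be positive")
    rng = _rng(seed)
    gene_ids = txome.gene_ids
    base = rng.lognormal(mean=0.0, sigma=0.5, size=len(gene_ids))
    rna_rows, rpf_rows = [], []
    for cond in ("WT", "KO"):
        for rep in range(1, n_replicates + 1):
            lam_rna = base * mean_rna
            mult = np.array([te_effects.get(g, 1.0) if cond == "KO" else 1.0
                             for g in gene_ids])
            lam_rpf = base * mean_rpf * mult
            rna = rng.poisson(lam_rna)
            rpf = rng.poisson(lam_rpf)
            for g, c in zip(gene_ids, rna):
                rna_rows.append((g, cond, rep, int(c)))
            for g, c in zip(gene_ids, rpf):
                rpf_rows.append((g, cond, rep, int(c)))
    cols = ["gene_id", "condition", "replicate", "count"]
    return pd.DataFrame(rna_rows, columns=cols), pd.DataFrame(rpf_rows, columns=cols)


# ---------------------------------------------------------------------------
# qPCR charging assay
# ---------------------------------------------------------------------------

def simulate_qpcr_ct(
    targets: dict[str, float],
    ct_noise_sd: float = 0.0,
    seed: int | None = 0,
    n_replicates: int = 3,
    spike_target: str = "yPhe",
    base_ct: float = 18.0,
    sample: str = "S1",
) -> pd.DataFrame:
    """Periodate-protection qPCR: Ct = base_ct - log2(template) + noise.

    In the oxidized reaction only the charged fraction of each tRNA target
    survives as template; the control reaction sees the full template; the
    spike-in target is unaffected by treatment.
    """
    for t, f in targets.items():
        if not (0 < f <= 1):
            raise InvalidConfigError(f"charged fraction for {t} must be in (0,1]")
    rng = _rng(seed)
    rows = []
    for treatment in ("oxidized", "control"):
        for target, frac in list(targets.items()) + [(spike_target, 1.0)]:
            template = 1.0
            if treatment == "oxidized" and target != spike_target:
                template = frac
            for rep in range(1, n_replicates + 1):
                ct = base_ct - math.log2(template)
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                rows.append((sample, target, treatment, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "target", "treatment", "replicate", "ct"])


# ---------------------------------------------------------------------------
# Dihybrid-cross cohorts
# ---------------------------------------------------------------------------

GENOTYPES = ("+/+", "+/-", "-/-")
MENDELIAN_PRIOR = {"+/+": 0.25, "+/-": 0.5, "-/-": 0.25}


@dataclass
class CohortModel:
    """Viability weights over the 9 Thumpd1 x Gcn2 genotype pairs.

    With all weights 1 the cross is purely Mendelian (1:2:1 per locus).
    Defaults are calibrated in closed form so that the expected Thumpd1-/-
    proportion is exactly 13% among offspring carrying a functional Gcn2
    allele and 22% among Gcn2-/- offspring:
    v = 13/29 and 11/13 respectively (solve 0.25 v / (0.75 + 0.25 v) = p).
    """

    viability: dict[tuple[str, str], float]

    def __post_init__(self):
        vals = [self.viability.get((t, g), 1.0) for t in GENOTYPES for g in GENOTYPES]
        if any(v < 0 for v in vals):
            raise InvalidConfigError("viability weights must be >= 0")
        if all(v == 0 for v in vals):
            raise InvalidConfigError("at least one viability weight must be > 0")

    @classmethod
    def mendelian(cls) -> "CohortModel":
        return cls(viability={(t, g): 1.0 for t in GENOTYPES for g in GENOTYPES})

    @classmethod
    def default(cls) -> "CohortModel":
        v = {(t, g): 1.0 for t in GENOTYPES for g in GENOTYPES}
        for g in ("+/+", "+/-"):
            v[("-/-", g)] = 13.0 / 29.0
        v[("-/-", "-/-")] = 11.0 / 13.0
        return cls(viability=v)

    def probabilities(self) -> pd.Series:
        idx = pd.MultiIndex.from_product([GENOTYPES, GENOTYPES], names=["thumpd1", "gcn2"])
        p = np.array([
            MENDELIAN_PRIOR[t] * MENDELIAN_PRIOR[g] * self.viability.get((t, g), 1.0)
            for t, g in idx
        ])
        if p.sum() <= 0:
            raise InvalidConfigError("all genotype probabilities are zero")
        return pd.Series(p / p.sum(), index=idx)


def simulate_cohort(n_offspring: int, model: CohortModel | None = None,
                    seed: int | None = 0) -> pd.DataFrame:
    """Draw a litter-pooled offspring cohort from the reweighted dihybrid
    prior.  Returns a GenotypeTable (thumpd1, gcn2, count) summing to
    ``n_offspring``."""
    if n_offspring < 1:
        raise InvalidConfigError("n_offspring must be >= 1")
    model = model or CohortModel.default()
    probs = model.probabilities()
    rng = _rng(seed)
    counts = rng.multinomial(n_offspring, probs.values)
    out = probs.index.to_frame(index=False)
    out["count"] = counts
    return out


# ---------------------------------------------------------------------------
# Sanger traces
# ---------------------------------------------------------------------------

def simulate_sanger_trace(
    true_rate: float,
    background: float,
    peak_scale: float = 1000.0,
    seed: int | None = 0,
    position: int = 12,
    noise_sd: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired Sanger peak tables (treated, water control) at one position.

    Treated T-peak share is ``true_rate + background`` (capped at 1); the
    water control shows only the background share.  Peak heights carry mild
    multiplicative noise but remain positive.
    """
    if not (0 <= true_rate <= 1 and 0 <= background <= 1):
        raise InvalidConfigError("rates must be in [0,1]")
    rng = _rng(seed)

    def table(t_share: float) -> pd.DataFrame:
        t_share = min(t_share, 1.0)
        rows = []
        for base, share in (("C", 1 - t_share), ("T", t_share), ("A", 0.0), ("G", 0.0)):
            h = share * peak_scale
            if h > 0 and noise_sd > 0:
                h *= math.exp(rng.normal(0.0, noise_sd))
            rows.append((position, base, h))
        return pd.DataFrame(rows, columns=["position", "base", "height"])

    return table(true_rate + background), table(background)
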