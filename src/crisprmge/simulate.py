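"""Synthetic metagenomic community with planted ground truth.

The generator emits a toy community in which every pipeline stage has a
known right answer: circular phage genomes; host genomes carrying CRISPR
arrays whose spacers sample their assigned phages (with a planted PAM
and configurable escape mutations applied to the phage copy); error-free
reads at fixed coverage; and contigs in which each phage appears
linearized with an exact terminal repeat, mimicking how an assembler
renders a completely assembled circular genome.

Targeting density is governed by ``protospacer_spacing``: each phage
receives roughly one sampled protospacer per ``protospacer_spacing``
bases (clamped into ``spacers_per_array``), positions stratified along
the circle so that coverage is even.  Real CRISPR-targeted elements are
targeted far more densely still (hundreds of protospacers on a ~50 kb
element); the stratification stands in for that density at toy scale so
that region chaining behaves as it would on real data.  Each phage
contig is linearized so that one sampled, never-escaped protospacer lies
inside the terminal repeat; on real dense data some protospacer always
falls in the redundant region, and this anchoring reproduces that
property deterministically.

All randomness derives from ``seed``; repeated runs are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hostpam import RANKS, Lineage
from .seqcore import Interval, SeqRecord, canonical, revcomp, write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# planted marker-gene labels cycled over phages, with the taxon each implies
_LABEL_CYCLE: list[tuple[tuple[str, ...], str]] = [
    (("HK97_capsid", "portal"), "Caudovirales"),
    (("Microviridae_MCP",), "Microviridae"),
    (("Inoviridae_MCP",), "Inoviridae"),
    (("ParA", "MobM"), "Plasmid-like"),
    ((), "Unclassified"),
]


@dataclass
class CommunityConfig:
    seed: int
    n_phages: int = 10
    phage_len_range: tuple[int, int] = (3_000, 40_000)
    n_hosts: int = 5
    host_len: int = 30_000
    n_phyla: int = 3
    spacers_per_array: tuple[int, int] = (12, 150)
    protospacer_spacing: int = 300
    dr_len_range: tuple[int, int] = (28, 36)
    spacer_len_range: tuple[int, int] = (30, 40)
    escape_rate: float = 0.05
    protospacer_mutations: int = 4
    tr_len: int = 55
    read_len: int = 200
    coverage: float = 15.0
    pam: str | None = "TTT"

    def __post_init__(self) -> None:
        for lo, hi in (self.phage_len_range, self.spacers_per_array,
                       self.dr_len_range, self.spacer_len_range):
            if lo >= hi:
                raise ValueError("config ranges must be non-degenerate")
        if self.spacer_len_range[1] + 3 > self.tr_len:
            raise ValueError("spacers must fit inside the terminal repeat")
        if self.spacer_len_range[1] > self.phage_len_range[0]:
            raise ValueError("spacer longer than smallest phage")


@dataclass
class TruthSpacer:
    host_id: str
    array_id: str
    dr_id: str
    seq: str                 # spacer as sampled (protospacer-strand 5'->3')
    phage_id: str
    interval: Interval       # protospacer on the phage circle
    mutated: bool

    @property
    def canonical_seq(self) -> str:
        return canonical(self.seq)


@dataclass
class TruthTable:
    """Ground truth of the generated community (see field comments)."""
    spacers: list[TruthSpacer]
    phage_seqs: dict[str, str]                 # circular sequences
    dr_by_array: dict[str, str]
    host_lineage: dict[str, Lineage]
    phage_host: dict[str, str]
    phage_rotation: dict[str, int]
    phage_labels: dict[str, tuple[str, ...]]   # planted marker genes
    phage_class: dict[str, str]                # taxon the labels imply
    array_interval: dict[str, Interval]        # array location on host
    read_origin: dict[str, tuple[str, int]]    # read id -> (genome id, start)

    def spacer_host_intervals(self) -> list[Interval]:
        """Host-genome interval of each truth spacer, in ``spacers`` order."""
        offsets: dict[str, int] = {}
        out: list[Interval] = []
        for t in self.spacers:
            dr_len = len(self.dr_by_array[t.array_id])
            base = self.array_interval[t.array_id].start
            off = offsets.get(t.array_id, dr_len)
            out.append(Interval(t.host_id, base + off, base + off + len(t.seq)))
            offsets[t.array_id] = off + len(t.seq) + dr_len
        return out

    def dr_spacer_dr_covered(self, read_len: int) -> list[bool]:
        """Whether >= 1 read fully spans DR-spacer-DR for each truth spacer."""
        host_ivals = self.spacer_host_intervals()
        starts_by_genome: dict[str, list[int]] = {}
        for _rid, (gid, start) in self.read_origin.items():
            starts_by_genome.setdefault(gid, []).append(start)
        for v in starts_by_genome.values():
            v.sort()
        out = []
        for t, iv in zip(self.spacers, host_ivals):
            dr_len = len(self.dr_by_array[t.array_id])
            lo, hi = iv.start - dr_len, iv.end + dr_len
            starts = starts_by_genome.get(t.host_id, [])
            out.append(any(s <= lo and s + read_len >= hi for s in starts))
        return out


@dataclass
class Community:
    config: CommunityConfig
    phages: list[SeqRecord]
    hosts: list[SeqRecord]
    contigs: list[SeqRecord]
    reads: list[SeqRecord]
    lineages: dict[str, Lineage]
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.phages, outdir / "phages.fasta")
        write_fasta(self.hosts, outdir / "hosts.fasta")
        write_fasta(self.contigs, outdir / "contigs.fasta")
        write_fastq(self.reads, outdir / "reads.fastq")
        rows = [{"genome_id": g, **{r: n or "" for r, n in
                                    zip(RANKS, lin.names)}}
                for g, lin in self.lineages.items()]
        pd.DataFrame(rows).to_csv(outdir / "lineages.tsv", sep="\t", index=False)
        truth_rows = [{
            "host_id": t.host_id, "array_id": t.array_id, "dr_id": t.dr_id,
            "spacer_seq": t.seq, "phage_id": t.phage_id,
            "start": t.interval.start, "end": t.interval.end,
            "strand": t.interval.strand, "mutated": t.mutated,
        } for t in self.truth.spacers]
        pd.DataFrame(truth_rows).to_csv(outdir / "truth_spacers.tsv",
                                        sep="\t", index=False)
        ann = [{"tr_id": pid, "gene_id": f"{pid}_g{i + 1}", "label": lab,
                "score": 100.0}
               for pid, labels in self.truth.phage_labels.items()
               for i, lab in enumerate(labels)]
        pd.DataFrame(ann, columns=["tr_id", "gene_id", "label", "score"]
                     ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def mutate_protospacer(seq: str, interval: Interval, n_mutations: int,
                       rng: np.random.Generator | int) -> str:
    """Exactly n_mutations substitutions inside the interval."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if interval.end > len(seq):
        raise ValueError("interval out of bounds")
    if n_mutations >= len(interval):
        raise ValueError("more mutations than interval positions")
    positions = rng.choice(np.arange(interval.start, interval.end),
                           size=n_mutations, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _toy_lineages(n_hosts: int, n_phyla: int) -> list[Lineage]:
    out = []
    for h in range(n_hosts):
        p = h % n_phyla
        out.append(Lineage((
            "Bacteria", f"Phylum_{chr(65 + p)}", f"Class_{chr(65 + p)}{h}",
            f"Order_{chr(65 + p)}{h}", f"Family_{chr(65 + p)}{h}",
            f"Genus_{chr(65 + p)}{h}", f"Species_{chr(65 + p)}{h}")))
    return out


def generate_community(config: CommunityConfig) -> Community:
    rng = np.random.default_rng(config.seed)
    cfg = config

    # --- circular phage genomes ---------------------------------------
    phage_seqs: dict[str, str] = {}
    for i in range(cfg.n_phages):
        length = int(rng.integers(cfg.phage_len_range[0],
                                  cfg.phage_len_range[1] + 1))
        phage_seqs[f"phage{i + 1:02d}"] = _random_seq(rng, length)

    lineage_list = _toy_lineages(cfg.n_hosts, cfg.n_phyla)
    host_ids = [f"host{h + 1:02d}" for h in range(cfg.n_hosts)]
    lineages = dict(zip(host_ids, lineage_list))
    phage_host = {pid: host_ids[i % cfg.n_hosts]
                  for i, pid in enumerate(phage_seqs)}

    # --- sample protospacers per phage (stratified along the circle) ---
    truth_spacers: list[TruthSpacer] = []
    dr_by_array: dict[str, str] = {}
    phage_rotation: dict[str, int] = {}
    arrays_by_host: dict[str, list[tuple[str, str, list[str]]]] = {
        h: [] for h in host_ids}
    pam = cfg.pam or ""
    for pid, seq in phage_seqs.items():
        L = len(seq)
        n_sp = int(np.clip(math.ceil(L / cfg.protospacer_spacing),
                           cfg.spacers_per_array[0], cfg.spacers_per_array[1]))
        stride = L / n_sp
        jitter = max(1, int(0.08 * stride))
        work = seq
        placements: list[tuple[int, int, str]] = []
        for j in range(n_sp):
            plen = int(rng.integers(cfg.spacer_len_range[0],
                                    cfg.spacer_len_range[1] + 1))
            start = (int(round(j * stride)) + int(rng.integers(jitter))) % L
            strand = "+" if rng.random() < 0.5 else "-"
            placements.append((start, plen, strand))
        # plant PAMs first (5' side in protospacer orientation), then
        # sample spacers, then apply escape mutations to the phage copy
        if pam:
            wl = list(work)
            for start, plen, strand in placements:
                if strand == "+":
                    for k, b in enumerate(pam):
                        wl[(start - len(pam) + k) % L] = b
                else:
                    rc = revcomp(pam)
                    for k, b in enumerate(rc):
                        wl[(start + plen + k) % L] = b
            work = "".join(wl)

        array_id = f"{pid}_array"
        dr = _random_seq(rng, int(rng.integers(cfg.dr_len_range[0],
                                               cfg.dr_len_range[1] + 1)))
        dr_by_array[array_id] = dr
        host_id = phage_host[pid]
        spacer_list: list[str] = []
        for j, (start, plen, strand) in enumerate(placements):
            end = start + plen  # may exceed L; sequence taken circularly
            proto = (work + work)[start:end]
            spacer = proto if strand == "+" else revcomp(proto)
            mutated = j > 0 and rng.random() < cfg.escape_rate
            if mutated:
                mut = mutate_protospacer(proto, Interval(pid, 0, plen),
                                         cfg.protospacer_mutations, rng)
                wl = list(work)
                for k in range(plen):
                    wl[(start + k) % L] = mut[k]
                work = "".join(wl)
            truth_spacers.append(TruthSpacer(
                host_id, array_id, array_id, spacer, pid,
                Interval(pid, start, end, strand), mutated))
            spacer_list.append(spacer)
        phage_seqs[pid] = work
        arrays_by_host[host_id].append((array_id, dr, spacer_list))
        # linearize anchored on the first (never-escaped) protospacer
        a_start, a_plen, _ = placements[0]
        offset = int(rng.integers(0, cfg.tr_len - a_plen + 1))
        phage_rotation[pid] = (a_start - offset) % L

    # --- host genomes with embedded arrays -----------------------------
    hosts: list[SeqRecord] = []
    array_interval: dict[str, Interval] = {}
    for host_id in host_ids:
        background = _random_seq(rng, cfg.host_len)
        arrays = arrays_by_host[host_id]
        blocks = []
        for array_id, dr, spacer_list in arrays:
            blocks.append((array_id,
                           dr + "".join(s + dr for s in spacer_list)))
        total = sum(len(b) for _, b in blocks)
        if total + 1000 * (len(blocks) + 1) > cfg.host_len:
            raise ValueError(
                f"host_len={cfg.host_len} too small for arrays ({total} b)")
        # place arrays left-to-right with random gaps, overwriting background
        free = cfg.host_len - total
        cuts = np.sort(rng.integers(500, free - 500, size=len(blocks)))
        out = list(background)
        shift = 0
        for (array_id, block), cut in zip(blocks, cuts):
            pos = int(cut) + shift
            out[pos:pos + len(block)] = block
            array_interval[array_id] = Interval(host_id, pos, pos + len(block))
            shift += len(block)
        hosts.append(SeqRecord(host_id, "".join(out)))

    # --- contigs: hosts as-is, phages linearized with terminal repeat --
    contigs: list[SeqRecord] = list(hosts)
    for pid, seq in phage_seqs.items():
        rot = phage_rotation[pid]
        lin = seq[rot:] + seq[:rot]
        contigs.append(SeqRecord(f"{pid}_contig", lin + lin[:cfg.tr_len]))

    # --- error-free reads at fixed coverage ----------------------------
    reads: list[SeqRecord] = []
    read_origin: dict[str, tuple[str, int]] = {}
    sources = hosts + [c for c in contigs if c.id.endswith("_contig")]
    for src in sources:
        n_reads = int(round(cfg.coverage * len(src.seq) / cfg.read_len))
        starts = rng.integers(0, len(src.seq) - cfg.read_len + 1, size=n_reads)
        flips = rng.random(n_reads) < 0.5
        for k, (s, flip) in enumerate(zip(starts, flips)):
            frag = src.seq[int(s):int(s) + cfg.read_len]
            rid = f"{src.id}_read{k + 1:06d}"
            reads.append(SeqRecord(rid, revcomp(frag) if flip else frag))
            read_origin[rid] = (src.id, int(s))

    labels = {pid: _LABEL_CYCLE[i % len(_LABEL_CYCLE)][0]
              for i, pid in enumerate(phage_seqs)}
    classes = {pid: _LABEL_CYCLE[i % len(_LABEL_CYCLE)][1]
               for i, pid in enumerate(phage_seqs)}

    truth = TruthTable(
        spacers=truth_spacers,
        phage_seqs=dict(phage_seqs),
        dr_by_array=dr_by_array,
        host_lineage=lineages,
        phage_host=phage_host,
        phage_rotation=phage_rotation,
        phage_labels=labels,
        phage_class=classes,
        array_interval=array_interval,
        read_origin=read_origin,
    )
    return Community(
        config=cfg,
        phages=[SeqRecord(pid, s) for pid, s in phage_seqs.items()],
        hosts=hosts,
        contigs=contigs,
        reads=reads,
        lineages=lineages,
        truth=truth,
    )


def random_orf_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + (n_codons-2) random non-stop codons + TAA."""
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)
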