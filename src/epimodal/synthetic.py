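"""Desk-scale synthetic fixtures with planted sequence and structure signal.

The generator emulates the statistical structure the multimodal method
assumes, at a scale where whole-genome matrices stay small:

* a random uniform-ACGT genome tiled into non-overlapping 200-bp bins,
  each described by a 1-kb neighbourhood sampled on both strands;
* one k-mer motif per event, planted into a configured fraction of bins
  (at non-overlapping slots inside the central bin, so plantings never
  clobber each other);
* a block-model Hi-C contact map: bins belong to round-robin communities,
  expected contacts are ``intra_rate`` within a community and
  ``inter_rate`` across, attenuated by a power-law distance decay within
  chromosomes, with Poisson counts (or exact expectations in
  ``expectation_mode``);
* binary event labels driven either by local sequence (motif planted in
  the bin) or by 3D structure (the bin's Hi-C community), the driver drawn
  per event with probability ``structure_beta``, plus independent label
  flips at rate ``label_noise``;
* variants: half destroy a planted motif occurrence by a single
  substitution ("effect"/pathogenic), half are background substitutions
  ("neutral"/benign), with eQTL-style increase/decrease signs derived from
  the generative rule, never from any model.

Everything regenerates byte-identically from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .genome_io import (
    BASES,
    GenomeAssembly,
    GenomicInterval,
    SequenceWindow,
    VariantRecord,
    tile_bins,
    windows_both_strands,
    write_bed,
    write_fasta,
    write_vcf,
)
from .hic_io import BinGrid, InteractionMatrix, write_contacts


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic fixtures.

    Defaults are desk-scale: 200-bp bins with 1-kb neighbourhoods (the
    published data model), but a 5-kb Hi-C resolution and short
    chromosomes so whole-genome graphs stay well under 1000 bins.
    """

    n_chroms: int = 4
    chrom_length: int = 20_000
    bin_length: int = 200
    window_length: int = 1000
    resolution: int = 5000
    n_events: int = 24
    motif_length: int = 8
    motif_fraction: float = 0.1
    n_communities: int = 4
    intra_rate: float = 10.0
    inter_rate: float = 1.0
    decay: float = 1.0
    structure_beta: float = 0.5  # probability an event is structure-driven
    label_noise: float = 0.05
    n_variants: int = 40
    seed: int = 0
    expectation_mode: bool = False

    def __post_init__(self):
        if not (0 <= self.structure_beta <= 1 and 0 <= self.label_noise <= 1):
            raise ValueError("structure_beta and label_noise must lie in [0, 1]")
        if min(self.intra_rate, self.inter_rate) < 0:
            raise ValueError("contact rates must be nonnegative")
        if self.motif_length > self.window_length:
            raise ValueError("motif longer than the window")
        if self.motif_length > self.bin_length:
            raise ValueError("motif must fit inside a bin")


@dataclass
class SyntheticVariant:
    record: VariantRecord
    is_effect: bool  # True: destroys a planted motif (pathogenic analogue)
    event: int | None  # the event whose motif was hit, if any
    eqtl_sign: int  # +1 increase / -1 decrease for effect variants, 0 neutral
    log2_fold_change: float


@dataclass
class Fixture:
    """A complete generated dataset, aligned across modalities.

    ``samples`` lists both-strand windows; sample ``2*i`` and ``2*i + 1``
    are the forward and reverse-complement views of forward bin ``i`` and
    share the label row.
    """

    config: SyntheticConfig
    assembly: GenomeAssembly
    bins: list[GenomicInterval]
    samples: list[SequenceWindow]
    grid: BinGrid
    matrix: InteractionMatrix
    communities: np.ndarray  # per Hi-C bin
    motifs: list[str]
    motif_presence: np.ndarray  # (n_forward_bins, E) bool
    drivers: np.ndarray  # per event: "seq" or "struct"
    event_communities: np.ndarray  # per event
    labels: np.ndarray  # (n_samples, E)
    sample_hic_bins: np.ndarray  # (n_samples,) global Hi-C bin per sample
    variants: list[SyntheticVariant]

    @property
    def sequences(self) -> list[str]:
        return [w.sequence for w in self.samples]

    @property
    def onehot(self) -> np.ndarray:
        return np.stack([w.onehot for w in self.samples])

    def sample_chroms(self) -> np.ndarray:
        return np.array([w.interval.chrom for w in self.samples])

    def structure_events(self) -> np.ndarray:
        return np.flatnonzero(self.drivers == "struct")

    def sequence_events(self) -> np.ndarray:
        return np.flatnonzero(self.drivers == "seq")


def _random_motifs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    motifs: list[str] = []
    while len(motifs) < n:
        m = "".join(rng.choice(list(BASES), size=length))
        if m not in motifs:
            motifs.append(m)
    return motifs


def generate_genome(config: SyntheticConfig, rng: np.random.Generator
                    ) -> tuple[GenomeAssembly, list[GenomicInterval], list[str], np.ndarray]:
    """Random background genome with motifs planted into bins.

    Returns (assembly, forward bins, motifs, presence matrix).  Motifs are
    written into non-overlapping slots of each bin's central 200 bp, so a
    planted occurrence is never partially overwritten by another.
    """
    if config.chrom_length < config.window_length:
        raise ValueError("chromosomes must be at least one window long")
    motifs = _random_motifs(rng, config.n_events, config.motif_length)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {
        c: rng.choice(list(BASES), size=config.chrom_length)
        for c in chrom_names
    }
    assembly = GenomeAssembly(chrom_names, {c: "".join(s) for c, s in seqs.items()})
    bins = tile_bins(assembly, config.bin_length, config.window_length)
    n_slots = config.bin_length // config.motif_length
    presence = np.zeros((len(bins), config.n_events), dtype=bool)
    arrays = {c: np.array(list(assembly.chrom_seqs[c])) for c in chrom_names}
    for b_idx, b in enumerate(bins):
        plant = rng.random(config.n_events) < config.motif_fraction
        events = np.flatnonzero(plant)
        if events.size == 0:
            continue
        slots = rng.choice(n_slots, size=min(events.size, n_slots), replace=False)
        for e, slot in zip(events[: slots.size], slots):
            start = b.start + slot * config.motif_length
            arrays[b.chrom][start : start + config.motif_length] = list(motifs[e])
            presence[b_idx, e] = True
    assembly = GenomeAssembly(chrom_names, {c: "".join(a) for c, a in arrays.items()})
    return assembly, bins, motifs, presence


def generate_hic(config: SyntheticConfig, grid: BinGrid,
                 rng: np.random.Generator) -> tuple[InteractionMatrix, np.ndarray]:
    """Block-model contact map with distance decay and Poisson noise."""
    n = grid.n_bins
    communities = np.arange(n) % config.n_communities
    chrom_of = np.empty(n, dtype=object)
    for c in grid.chrom_names:
        off = grid.offsets[c]
        chrom_of[off : off + grid.bins_per_chrom[c]] = c
    same_comm = communities[:, None] == communities[None, :]
    rate = np.where(same_comm, config.intra_rate, config.inter_rate).astype(float)
    same_chrom = chrom_of[:, None] == chrom_of[None, :]
    dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    decay = np.where(same_chrom, (1.0 + dist) ** (-config.decay), 1.0)
    expected = rate * decay
    if config.expectation_mode:
        values = expected
    else:
        upper = rng.poisson(np.triu(expected))
        values = upper + np.triu(upper, 1).T
    matrix = InteractionMatrix(grid, sp.csr_matrix(np.asarray(values, dtype=float)))
    return matrix, communities


def generate_labels(config: SyntheticConfig, bins, presence: np.ndarray,
                    communities: np.ndarray, grid: BinGrid,
                    rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-forward-bin labels plus the event drivers and communities."""
    E = config.n_events
    drivers = np.where(rng.random(E) < config.structure_beta, "struct", "seq")
    event_communities = np.arange(E) % config.n_communities
    n = len(bins)
    labels = np.zeros((n, E), dtype=np.int8)
    hic_bin = np.array([grid.bin_of_interval(b.chrom, b.start, b.end) for b in bins])
    for e in range(E):
        if drivers[e] == "seq":
            labels[:, e] = presence[:, e]
        else:
            labels[:, e] = communities[hic_bin] == event_communities[e]
    flips = rng.random(labels.shape) < config.label_noise
    labels = labels ^ flips
    return labels.astype(np.int8), drivers, event_communities


def generate_variants(config: SyntheticConfig, assembly: GenomeAssembly,
                      bins, motifs, presence: np.ndarray,
                      rng: np.random.Generator) -> list[SyntheticVariant]:
    """Half motif-destroying ("effect"), half background ("neutral")."""
    half = config.n_variants // 2
    flank = config.window_length // 2
    lengths = assembly.chrom_lengths
    eligible = [
        (i, b) for i, b in enumerate(bins)
        if b.start >= flank and b.end + flank <= lengths[b.chrom]
    ]
    with_motif = [(i, b) for i, b in eligible if presence[i].any()]
    # each planted occurrence offers motif_length distinct substitution sites
    if len(with_motif) * config.motif_length < half:
        raise ValueError("not enough motif-bearing bins for the requested variants")
    out: list[SyntheticVariant] = []
    used: set[tuple[str, int]] = set()
    k = 0
    guard = 0
    while len(out) < half:
        guard += 1
        if guard > 200 * config.n_variants:
            raise RuntimeError("failed to place motif-destroying variants")
        b_idx, b = with_motif[int(rng.integers(len(with_motif)))]
        events = np.flatnonzero(presence[b_idx])
        e = int(rng.choice(events))
        motif = motifs[e]
        seq = assembly.chrom_seqs[b.chrom]
        occ = seq.find(motif, b.start, b.end)
        if occ < 0:
            continue
        pos = occ + int(rng.integers(len(motif)))
        if (b.chrom, pos) in used:
            continue
        ref = seq[pos]
        alt = rng.choice([x for x in BASES if x != ref])
        sign = 1 if e % 2 == 0 else -1
        out.append(SyntheticVariant(
            record=VariantRecord(b.chrom, pos, ref, str(alt), id=f"eff{k}"),
            is_effect=True, event=e, eqtl_sign=sign,
            log2_fold_change=sign * float(2.0 + rng.exponential(1.0)),
        ))
        used.add((b.chrom, pos))
        k += 1
    n_neutral = config.n_variants - half
    k = 0
    guard = 0
    while k < n_neutral:
        guard += 1
        if guard > 100 * config.n_variants:
            raise RuntimeError("failed to place neutral variants")
        b_idx, b = eligible[int(rng.integers(len(eligible)))]
        pos = int(rng.integers(b.start, b.end))
        if (b.chrom, pos) in used:
            continue
        # keep neutral substitutions outside every planted motif occurrence
        in_motif = False
        for e in np.flatnonzero(presence[b_idx]):
            occ = assembly.chrom_seqs[b.chrom].find(motifs[e], b.start, b.end)
            if occ >= 0 and occ <= pos < occ + len(motifs[e]):
                in_motif = True
                break
        if in_motif:
            continue
        ref = assembly.chrom_seqs[b.chrom][pos]
        alt = rng.choice([x for x in BASES if x != ref])
        out.append(SyntheticVariant(
            record=VariantRecord(b.chrom, pos, ref, str(alt), id=f"neu{k}"),
            is_effect=False, event=None, eqtl_sign=0,
            log2_fold_change=float(rng.normal(0.0, 0.3)),
        ))
        used.add((b.chrom, pos))
        k += 1
    return out


def generate_fixture(config: SyntheticConfig) -> Fixture:
    """Generate the full aligned fixture from (config, seed)."""
    rng = np.random.default_rng(config.seed)
    assembly, bins, motifs, presence = generate_genome(config, rng)
    grid = BinGrid.from_assembly(assembly, config.resolution)
    matrix, communities = generate_hic(config, grid, rng)
    bin_labels, drivers, event_communities = generate_labels(
        config, bins, presence, communities, grid, rng
    )
    samples = windows_both_strands(assembly, bins, config.window_length)
    if len(samples) != 2 * len(bins):
        raise AssertionError("window doubling misaligned with bins")
    labels = np.repeat(bin_labels, 2, axis=0)  # both strands share the label row
    hic_per_bin = np.array([grid.bin_of_interval(b.chrom, b.start, b.end) for b in bins])
    sample_hic = np.repeat(hic_per_bin, 2)
    variants = generate_variants(config, assembly, bins, motifs, presence, rng)
    return Fixture(
        config=config, assembly=assembly, bins=bins, samples=samples, grid=grid,
        matrix=matrix, communities=communities, motifs=motifs,
        motif_presence=presence, drivers=drivers,
        event_communities=event_communities, labels=labels,
        sample_hic_bins=sample_hic, variants=variants,
    )


def write_fixture(fixture: Fixture, outdir) -> None:
    """Write FASTA + BED + contact TSV + label TSV + variant TSV + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(fixture.assembly, outdir / "genome.fa")
    write_bed((w.interval for w in fixture.samples), outdir / "windows.bed")
    write_contacts(fixture.matrix, outdir / "contacts.tsv", format="coo")
    with open(outdir / "labels.tsv", "w") as fh:
        header = "\t".join(f"event_{e}" for e in range(fixture.labels.shape[1]))
        fh.write(f"window\t{header}\n")
        for w, row in zip(fixture.samples, fixture.labels):
            wid = f"{w.interval.chrom}:{w.interval.start}-{w.interval.end}:{w.interval.strand}"
            fh.write(wid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    write_vcf((v.record for v in fixture.variants), outdir / "variants.vcf")
    with open(outdir / "variant_labels.tsv", "w") as fh:
        fh.write("id\tis_effect\tevent\teqtl_sign\tlog2_fold_change\n")
        for v in fixture.variants:
            fh.write(
                f"{v.record.id}\t{int(v.is_effect)}\t"
                f"{'' if v.event is None else v.event}\t{v.eqtl_sign}\t"
                f"{v.log2_fold_change:.6f}\n"
            )
    manifest = dataclasses.asdict(fixture.config)
    manifest["drivers"] = fixture.drivers.tolist()
    manifest["motifs"] = fixture.motifs
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_labels_tsv(path) -> tuple[list[str], np.ndarray]:
    ids, rows = [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([int(v) for v in parts[1:]])
    return ids, np.asarray(rows, dtype=np.int8)
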