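"""Ground-truthed synthetic library generator.

Builds a random reference with an implanted on-target protospacer and
optional cryptic off-target sites, draws molecules from a configurable
outcome mixture, attaches 14-nt random molecular barcodes, amplifies
with Poisson PCR duplication and a per-base substitution error model,
and formats paired reads:

* read 1 — bait primer onward, across the cut into the repair partner;
* read 2 — bridge adapter (flank, RMB, flank) then the reverse
  complement of the fragment, read from its far end.

Everything is driven by one integer seed; identical seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .genome import Genome, decode, encode, revcomp_codes
from .junctions import BaitConfig
from .preprocess import AdapterSpec, RawReadPair, RMB_LENGTH

__all__ = [
    "OffTargetSpec",
    "SimSpec",
    "TruthRecord",
    "SimulatedLibrary",
    "make_genome",
    "simulate_molecules",
    "amplify_and_sequence",
    "simulate_library",
]

MOLECULE_CATEGORIES = (
    "germline",
    "small_insertion",
    "small_deletion",
    "large_deletion",
    "inversion",
    "resection",
    "offtarget_translocation",
    "background_translocation",
)

#: truth category/subcategory the pipeline should recover per molecule kind.
TRUE_CLASS = {
    "germline": ("germline", "perfect"),
    "small_insertion": ("indel", "small_insertion"),
    "small_deletion": ("indel", "small_deletion"),
    "large_deletion": ("indel", "large_deletion"),
    "inversion": ("indel", "inversion"),
    "resection": ("indel", "large_deletion"),
    "offtarget_translocation": ("translocation", "offtarget_translocation"),
    "background_translocation": ("translocation", "background_translocation"),
}


@dataclass(frozen=True)
class OffTargetSpec:
    chrom: str
    cut_pos: int
    mismatches: int = 3
    pam: str = "NGG"  # concrete PAM written into the genome, or "none"
    junction_mass: float = 1.0


@dataclass
class SimSpec:
    genome_sizes: dict[str, int]
    seed: int
    guide_seq: str
    bait_chrom: str
    bait_cut_pos: int
    mixture: dict[str, float]
    offtargets: tuple[OffTargetSpec, ...] = ()
    primer_offset: int = 80  # primer start, bp upstream of the cut
    primer_len: int = 20
    n_molecules: int = 1000
    duplication_mean: float = 0.0
    error_rate: float = 0.0
    fragment_range: tuple[int, int] = (300, 2000)
    read_len: int = 150
    proximal_range: tuple[int, int] = (1_000, 200_000)
    resection_range: tuple[int, int] = (5_000, 50_000)
    insertion_range: tuple[int, int] = (1, 10)
    deletion_range: tuple[int, int] = (1, 15)
    exclusion_span: int = 250_000
    offtarget_jitter: int = 5
    index_seq: str = "ACGTACGT"

    def __post_init__(self) -> None:
        unknown = set(self.mixture) - set(MOLECULE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown mixture categories: {sorted(unknown)}")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture must sum to 1, got {total}")
        if any(v < 0 for v in self.mixture.values()):
            raise ValueError("mixture masses must be non-negative")

    def bait_config(self, adapter: Optional[AdapterSpec] = None) -> BaitConfig:
        start = self.bait_cut_pos - self.primer_offset
        return BaitConfig(
            chrom=self.bait_chrom,
            strand="+",
            primer_start=start,
            primer_end=start + self.primer_len,
            cut_pos=self.bait_cut_pos,
            guide_seq=self.guide_seq,
        )


@dataclass
class TruthRecord:
    molecule_id: str
    rmb: str
    kind: str
    category: str
    subcategory: str
    prey_chrom: Optional[str]
    prey_coord: Optional[int]
    prey_strand: Optional[str]
    n_copies: int = 1


@dataclass
class SimulatedLibrary:
    spec: SimSpec
    genome: Genome
    bait: BaitConfig
    adapter: AdapterSpec
    truth: list[TruthRecord]
    pairs: list[RawReadPair]
    offtarget_cuts: list[OffTargetSpec]


def _mutate_protospacer(rng: np.random.Generator, proto: np.ndarray, n_mm: int) -> np.ndarray:
    out = proto.copy()
    if n_mm == 0:
        return out
    positions = rng.choice(len(proto), size=n_mm, replace=False)
    for p in positions:
        out[p] = (out[p] + rng.integers(1, 4)) % 4
    return out


def make_genome(spec: SimSpec) -> tuple[Genome, list[OffTargetSpec]]:
    """Random genome with the on-target site and off-targets implanted.

    Every site is written on the plus strand as protospacer + PAM with
    the cut 3 bp 5' of the PAM; an off-target with ``pam="none"`` gets a
    cleavage-incompetent PAM (no NGG/NAG readable on either frame).
    Returns the genome and the realized off-target list.
    """
    rng = np.random.default_rng(spec.seed)
    arrays = {
        name: rng.integers(0, 4, size=size, dtype=np.uint8)
        for name, size in spec.genome_sizes.items()
    }
    guide = encode(spec.guide_seq)

    def implant(chrom: str, cut: int, proto: np.ndarray, pam: str) -> None:
        start = cut - 17
        arr = arrays[chrom]
        arr[start : start + 20] = proto
        pam_codes = encode("TTT") if pam == "none" else encode(pam.replace("N", "ACGT"[rng.integers(0, 4)]))
        arr[start + 20 : start + 20 + len(pam_codes)] = pam_codes

    implant(spec.bait_chrom, spec.bait_cut_pos, guide, "NGG")
    realized = []
    for ot in spec.offtargets:
        proto = _mutate_protospacer(rng, guide, ot.mismatches)
        implant(ot.chrom, ot.cut_pos, proto, ot.pam)
        realized.append(ot)
    return Genome(arrays), realized


def _random_rmb(rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=RMB_LENGTH, dtype=np.uint8))


def simulate_molecules(
    spec: SimSpec, genome: Genome, rng: np.random.Generator
) -> tuple[list[TruthRecord], list[np.ndarray]]:
    """Draw molecules (code arrays, primer first) and their truth records."""
    bait = spec.bait_config()
    arr = genome.codes(spec.bait_chrom)
    cut = spec.bait_cut_pos
    p0 = bait.primer_start
    bait_len = cut - p0
    names = [c for c in spec.mixture]
    probs = np.array([spec.mixture[c] for c in names])
    ot_masses = np.array([ot.junction_mass for ot in spec.offtargets], dtype=float)
    if ot_masses.sum() > 0:
        ot_masses = ot_masses / ot_masses.sum()
    truth: list[TruthRecord] = []
    molecules: list[np.ndarray] = []
    chrom_names = genome.chrom_names
    chrom_sizes = genome.sizes
    for i in range(spec.n_molecules):
        kind = names[int(rng.choice(len(names), p=probs))]
        frag = int(rng.integers(spec.fragment_range[0], spec.fragment_range[1] + 1))
        rmb = _random_rmb(rng)
        prey_chrom = prey_coord = prey_strand = None
        if kind == "germline":
            mol = arr[p0 : p0 + frag].copy()
        elif kind == "small_insertion":
            ins_len = int(rng.integers(spec.insertion_range[0], spec.insertion_range[1] + 1))
            ins = rng.integers(0, 4, size=ins_len, dtype=np.uint8)
            rest = frag - bait_len - len(ins)
            mol = np.concatenate([arr[p0:cut], ins, arr[cut : cut + rest]])
        elif kind == "small_deletion":
            dlen = int(rng.integers(spec.deletion_range[0], spec.deletion_range[1] + 1))
            d_left = int(rng.integers(0, dlen + 1))
            lo, hi = cut - d_left, cut + (dlen - d_left)
            mol = np.concatenate([arr[p0:lo], arr[hi : hi + (frag - (lo - p0))]])
        elif kind in ("large_deletion", "resection"):
            span = spec.resection_range if kind == "resection" else spec.proximal_range
            dist = int(np.exp(rng.uniform(np.log(span[0]), np.log(span[1]))))
            dist = min(max(dist, span[0]), span[1])
            prey_chrom, prey_coord, prey_strand = spec.bait_chrom, cut + dist, "+"
            rest = frag - bait_len
            mol = np.concatenate([arr[p0:cut], arr[prey_coord : prey_coord + rest]])
        elif kind == "inversion":
            dist = int(np.exp(rng.uniform(np.log(spec.proximal_range[0]), np.log(spec.proximal_range[1]))))
            prey_chrom, prey_coord, prey_strand = spec.bait_chrom, cut + dist, "-"
            rest = frag - bait_len
            mol = np.concatenate([arr[p0:cut], revcomp_codes(arr[prey_coord - rest : prey_coord])])
        elif kind == "offtarget_translocation":
            if not spec.offtargets:
                raise ValueError("offtarget_translocation mass requires offtargets")
            ot = spec.offtargets[int(rng.choice(len(spec.offtargets), p=ot_masses))]
            jitter = int(rng.integers(-spec.offtarget_jitter, spec.offtarget_jitter + 1))
            prey_chrom = ot.chrom
            prey_coord = ot.cut_pos + jitter
            prey_strand = "+" if rng.random() < 0.5 else "-"
            mol = _join_prey(genome, arr, p0, cut, frag, prey_chrom, prey_coord, prey_strand)
        elif kind == "background_translocation":
            while True:
                prey_chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                margin = frag + 10
                prey_coord = int(rng.integers(margin, chrom_sizes[prey_chrom] - margin))
                if prey_chrom == spec.bait_chrom and abs(prey_coord - cut) <= spec.exclusion_span:
                    continue
                break
            prey_strand = "+" if rng.random() < 0.5 else "-"
            mol = _join_prey(genome, arr, p0, cut, frag, prey_chrom, prey_coord, prey_strand)
        else:  # pragma: no cover
            raise AssertionError(kind)
        category, subcategory = TRUE_CLASS[kind]
        truth.append(
            TruthRecord(
                molecule_id=f"M{i:07d}",
                rmb=rmb,
                kind=kind,
                category=category,
                subcategory=subcategory,
                prey_chrom=prey_chrom,
                prey_coord=prey_coord,
                prey_strand=prey_strand,
            )
        )
        molecules.append(mol)
    return truth, molecules


def _join_prey(
    genome: Genome,
    bait_arr: np.ndarray,
    p0: int,
    cut: int,
    frag: int,
    prey_chrom: str,
    prey_coord: int,
    prey_strand: str,
) -> np.ndarray:
    rest = frag - (cut - p0)
    parr = genome.codes(prey_chrom)
    if prey_strand == "+":
        prey_part = parr[prey_coord : prey_coord + rest]
    else:
        prey_part = revcomp_codes(parr[max(0, prey_coord - rest) : prey_coord])
    return np.concatenate([bait_arr[p0:cut], prey_part])


def amplify_and_sequence(
    truth: list[TruthRecord],
    molecules: Sequence[np.ndarray],
    spec: SimSpec,
    adapter: AdapterSpec,
    rng: np.random.Generator,
) -> list[RawReadPair]:
    """PCR-duplicate and read out each molecule as a 2x``read_len`` pair.

    Copy count is 1 + Poisson(duplication_mean); substitution errors hit
    every base of every copy independently — including the barcode, so
    duplicate reads of one molecule can disagree in their RMB.
    """
    bridge5 = encode(adapter.bridge_flank5)
    bridge3 = encode(adapter.bridge_flank3)
    pairs: list[RawReadPair] = []
    q40 = None
    for rec, mol in zip(truth, molecules):
        n_copies = 1 + int(rng.poisson(spec.duplication_mean))
        rec.n_copies = n_copies
        rmb_codes = encode(rec.rmb)
        for c in range(n_copies):
            template = np.concatenate([mol, rmb_codes])
            if spec.error_rate > 0:
                errs = np.nonzero(rng.random(len(template)) < spec.error_rate)[0]
                for e in errs:
                    template[e] = (template[e] + rng.integers(1, 4)) % 4
            mol_c, rmb_c = template[: len(mol)], template[len(mol) :]
            read1 = mol_c[: spec.read_len]
            r2_full = np.concatenate([bridge5, rmb_c, bridge3, revcomp_codes(mol_c)])
            read2 = r2_full[: spec.read_len]
            if q40 is None or len(q40) < max(len(read1), len(read2)):
                q40 = [40] * max(len(read1), len(read2))
            pairs.append(
                RawReadPair(
                    read_id=f"{rec.molecule_id}.C{c}",
                    read1_seq=decode(read1),
                    read1_quals=q40[: len(read1)],
                    read2_seq=decode(read2),
                    read2_quals=q40[: len(read2)],
                    index_seq=spec.index_seq,
                )
            )
    return pairs


def simulate_library(
    spec: SimSpec,
    adapter: Optional[AdapterSpec] = None,
    genome: Optional[Genome] = None,
    molecule_seed: Optional[int] = None,
) -> SimulatedLibrary:
    """End-to-end synthesis: genome, molecules, amplified read pairs.

    Pass an existing ``genome`` (with ``molecule_seed``) to simulate a
    second library — e.g. an uncut control — against the same reference.
    """
    if genome is None:
        genome, offtargets = make_genome(spec)
    else:
        offtargets = list(spec.offtargets)
    bait = spec.bait_config()
    adapter = adapter or AdapterSpec(
        bait_primer=genome.fetch(bait.chrom, bait.primer_start, bait.primer_end)
    )
    rng = np.random.default_rng(spec.seed + 1 if molecule_seed is None else molecule_seed)
    truth, molecules = simulate_molecules(spec, genome, rng)
    pairs = amplify_and_sequence(truth, molecules, spec, adapter, rng)
    return SimulatedLibrary(
        spec=spec,
        genome=genome,
        bait=bait,
        adapter=adapter,
        truth=truth,
        pairs=pairs,
        offtarget_cuts=list(offtargets),
    )


def control_spec(spec: SimSpec) -> SimSpec:
    """An uncut-control twin of ``spec``: 100% germline mixture.

    Simulate it against the sample's genome object (or the same genome
    seed) so both libraries share one reference.
    """
    return replace(spec, mixture={"germline": 1.0})
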