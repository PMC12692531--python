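"""Synthetic transcriptomes and simulated scans with known ground truth.

The generator emulates the sequence features that make probe design hard on a
paleotetraploid fish transcriptome: multi-isoform genes (isoform counts drawn
from a two-to-fourteen range, isoforms sharing exon subsets with distinct
compositions), high-identity paralog families (globin-like), poly(A) tails,
and vector/low-complexity contamination. The scan simulator produces
feature-extraction-style per-spot tables from a layout plus a ground-truth
expression table: median signal is gain * 2^expr with log-normal
multiplicative noise plus a truncated-Gaussian background draw, and QC flags
are injected at configurable rates.

Two presets package the platform's validation designs end to end: a
three-array self-self dye-balance experiment and a two-isolation technical
reproducibility experiment (8 vs 8 single-channel arrays with 12 probes
shifted by +1.23 log2 units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import SPIKEIN_LEVELS, ArrayLayout, LayoutSpec, build_layout
from .probe_design import ProbeRecord

__all__ = [
    "SyntheticTranscriptomeParams",
    "NoiseModel",
    "FlagRates",
    "SyntheticTruth",
    "SYNTHETIC_VECTOR",
    "generate_transcriptome",
    "simulate_scan",
    "preset_selfself",
    "preset_two_isolations",
    "spikein_expected_ratios",
]

_BASES = np.array(list("ACGT"))

#: synthetic cloning-vector segment used for contamination injection (labelled
#: synthetic: not a real vector sequence)
SYNTHETIC_VECTOR = (
    "GCTAGCTTGGTACCGAGCTCGGATCCACTAGTCCAGTGTGGTGGAATTCTGCAGATATCC"
    "AGCACAGTGGCGGCCGCTCGAGTCTAGAGGGCCCGTTTAAACCCGCTGATCAGCCTCGAC"
)


@dataclass(frozen=True)
class SyntheticTranscriptomeParams:
    n_genes: int = 50
    isoform_range: tuple[int, int] = (2, 14)
    paralog_families: int = 1
    paralog_family_size: int = 2
    paralog_identity: float = 0.92
    polyA_length: int = 30
    vector_injection_rate: float = 0.04
    repeat_injection_rate: float = 0.04
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (60, 200)
    biotype_probs: tuple[float, float, float] = (0.874, 0.122, 0.004)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.isoform_range
        if not (1 <= lo <= hi <= 14):
            raise ValueError("isoform_range must lie within [1, 14]")
        if not 0.0 < self.paralog_identity <= 1.0:
            raise ValueError("paralog identity must be in (0, 1]")


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate(rng, seq: str, identity: float) -> str:
    """Uniform random point mutation to the target identity."""
    out = list(seq)
    n_mut = int(round(len(seq) * (1.0 - identity)))
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def _gene_structure(rng, params: SyntheticTranscriptomeParams, exon_seqs=None):
    lo, hi = params.isoform_range
    n_iso = int(rng.integers(lo, hi + 1))
    if exon_seqs is None:
        n_exons = max(3, min(n_iso + 1, 9))
        exon_seqs = [
            _random_seq(rng, int(rng.integers(*params.exon_length_range)))
            for _ in range(n_exons)
        ]
    else:
        n_exons = len(exon_seqs)
    introns = [
        _random_seq(rng, int(rng.integers(*params.intron_length_range)))
        for _ in range(n_exons - 1)
    ]
    # isoform 1 keeps all exons (the longest); others drop distinct subsets
    internal = list(range(1, n_exons - 1))
    compositions = [tuple(range(n_exons))]
    attempts = 0
    while len(compositions) < n_iso and attempts < 200:
        attempts += 1
        k = int(rng.integers(1, max(2, len(internal) + 1)))
        drop = set(rng.choice(internal, size=min(k, len(internal)), replace=False))
        comp = tuple(i for i in range(n_exons) if i not in drop)
        if comp not in compositions:
            compositions.append(comp)
    return exon_seqs, introns, compositions


def generate_transcriptome(
    params: SyntheticTranscriptomeParams, out_dir
) -> tuple[Path, Path]:
    """Write a synthetic genome FASTA + GFF3 pair; deterministic under seed.

    One contig per gene; the poly(A) tail is part of the terminal exon so
    spliced transcripts end in A-runs as oligo(dT)-primed cDNA would.
    Returns (fasta_path, gff3_path).
    """
    rng = np.random.default_rng(params.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "transcriptome.fa"
    gff_path = out_dir / "transcriptome.gff3"

    biotypes = ("mRNA", "ncRNA", "miscRNA")
    fasta_lines: list[str] = []
    gff_lines = ["##gff-version 3"]

    # paralog families reuse a base gene's exon sequences, mutated
    plain = max(params.n_genes - params.paralog_families * (params.paralog_family_size - 1), 1)
    n_bases = min(params.paralog_families, plain)
    base_positions = {int(b) + 1 for b in rng.choice(plain, size=n_bases, replace=False)}

    base_exons_store: list[list[str]] = []
    for gi in range(1, plain + 1):
        exon_seqs, introns, comps = _gene_structure(rng, params)
        exon_seqs = _emit_gene(
            rng, params, gi, exon_seqs, introns, comps, fasta_lines, gff_lines, biotypes
        )
        if gi in base_positions:
            base_exons_store.append(exon_seqs)

    # family members: mutated copies of a base gene's (post-injection) exons
    written = plain
    for exon_seqs in base_exons_store:
        for _ in range(params.paralog_family_size - 1):
            written += 1
            mut_exons = [_mutate(rng, e, params.paralog_identity) for e in exon_seqs]
            _, introns, comps = _gene_structure(rng, params, exon_seqs=mut_exons)
            _emit_gene(
                rng, params, written, mut_exons, introns, comps, fasta_lines, gff_lines, biotypes
            )

    fasta_path.write_text("".join(fasta_lines))
    gff_path.write_text("\n".join(gff_lines) + "\n")
    return fasta_path, gff_path


def _emit_gene(rng, params, gi, exon_seqs, introns, comps, fasta_lines, gff_lines, biotypes):
    gene_id = f"gene{gi:04d}"
    contig = f"ctg{gi:04d}"
    exon_seqs = list(exon_seqs)
    # contamination: vector substring or low-complexity repeat inside an exon
    if rng.random() < params.vector_injection_rate and len(exon_seqs[0]) > 80:
        e = exon_seqs[0]
        vlen = min(60, len(SYNTHETIC_VECTOR))
        pos = int(rng.integers(0, len(e) - vlen))
        exon_seqs[0] = e[:pos] + SYNTHETIC_VECTOR[:vlen] + e[pos + vlen :]
    if rng.random() < params.repeat_injection_rate and len(exon_seqs[-2 if len(exon_seqs) > 1 else 0]) > 100:
        idx = -2 if len(exon_seqs) > 1 else 0
        e = exon_seqs[idx]
        rep = "AT" * 30
        pos = int(rng.integers(0, len(e) - len(rep)))
        exon_seqs[idx] = e[:pos] + rep + e[pos + len(rep) :]
    core_exons = list(exon_seqs)  # pre-poly(A), reused for paralog members
    exon_seqs[-1] = exon_seqs[-1] + "A" * params.polyA_length

    genome_parts = []
    exon_coords = []
    cursor = 1  # 1-based
    for i, e in enumerate(exon_seqs):
        exon_coords.append((cursor, cursor + len(e) - 1))
        genome_parts.append(e)
        if i < len(exon_seqs) - 1:
            genome_parts.append(introns[i])
            cursor += len(e) + len(introns[i])
        else:
            cursor += len(e)
    genome = "".join(genome_parts)
    fasta_lines.append(f">{contig}\n")
    for i in range(0, len(genome), 70):
        fasta_lines.append(genome[i : i + 70] + "\n")

    biotype = biotypes[int(rng.choice(3, p=params.biotype_probs))]
    gff_lines.append(
        f"{contig}\tsynth\tgene\t1\t{len(genome)}\t.\t+\t.\tID={gene_id}"
    )
    for ti, comp in enumerate(comps, start=1):
        tx_id = f"{gene_id}.t{ti}"
        t_start = exon_coords[comp[0]][0]
        t_end = exon_coords[comp[-1]][1]
        ftype = "mRNA" if biotype == "mRNA" else ("ncRNA" if biotype == "ncRNA" else "misc_RNA")
        gff_lines.append(
            f"{contig}\tsynth\t{ftype}\t{t_start}\t{t_end}\t.\t+\t.\t"
            f"ID={tx_id};Parent={gene_id};biotype={biotype}"
        )
        for ei in comp:
            s, e = exon_coords[ei]
            gff_lines.append(
                f"{contig}\tsynth\texon\t{s}\t{e}\t.\t+\t.\tID={tx_id}.e{ei};Parent={tx_id}"
            )
    return core_exons


# ---------------------------------------------------------------------------
# scan simulation


@dataclass(frozen=True)
class NoiseModel:
    gain: float = 1.0
    bg_mean: float = 50.0
    bg_sd: float = 10.0
    mult_sigma_log2: float = 0.25  # sd of multiplicative noise, log2 scale

    @property
    def mult_sigma_ln(self) -> float:
        return self.mult_sigma_log2 * np.log(2.0)


@dataclass(frozen=True)
class FlagRates:
    nonunif: float = 0.001
    popn: float = 0.001
    saturated: float = 0.0


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated experiment, addressable by feature id."""

    expr: dict[tuple[str, str], pd.Series]  # (array_id, channel) -> log2 expr
    differential: dict[str, float] = field(default_factory=dict)
    dye_offsets: pd.Series | None = None
    spike_expected: pd.Series | None = None
    seed: int = 0


def spikein_expected_ratios(levels: int = SPIKEIN_LEVELS, span: float = 2.0) -> np.ndarray:
    """Declared expected log2 red/green ratios of the spike-in series,
    spanning -span..+span across the dilution levels."""
    return np.linspace(-span, span, levels)


def _spikein_level(feature_id: str) -> int:
    # E1A_L03_001 -> level 3 (1-based)
    return int(feature_id.split("_")[1][1:])


def simulate_scan(
    layout: ArrayLayout,
    truth: SyntheticTruth,
    array_id: str,
    noise: NoiseModel | None = None,
    flags: FlagRates | None = None,
    rng: np.random.Generator | None = None,
    subarray: int = 0,
) -> pd.DataFrame:
    """Simulate one feature-extraction-style table for one (sub)array.

    median_signal = gain * 2^expr * mult_noise + background draw; background
    median and pixel-SD columns come from the background model; processed
    signal is the background-corrected median floored at 1.0. Deterministic
    for a given generator state.
    """
    noise = noise or NoiseModel()
    flags = flags or FlagRates()
    rng = rng or np.random.default_rng(truth.seed)
    sub = layout.subarrays[subarray]
    n = len(sub)
    ids = sub["feature_id"].to_numpy()
    classes = sub["feature_class"].to_numpy()

    frame = pd.DataFrame({"ProbeID": ids, "feature_class": classes})
    for channel, prefix in (("green", "g"), ("red", "r")):
        expr = truth.expr.get((array_id, channel))
        if expr is None:
            raise ValueError(f"truth missing channel {channel!r} for array {array_id!r}")
        missing = [i for i in np.unique(ids) if i not in expr.index]
        if missing:
            raise ValueError(f"truth missing features: {missing[:5]}")
        e = expr.reindex(ids).to_numpy(dtype=float)
        mult = np.exp(rng.normal(0.0, noise.mult_sigma_ln, size=n)) if noise.mult_sigma_ln > 0 else 1.0
        bg_draw = np.clip(rng.normal(noise.bg_mean, noise.bg_sd, size=n), 0.0, None) if noise.bg_sd > 0 else np.full(n, noise.bg_mean)
        bg_median = np.clip(rng.normal(noise.bg_mean, noise.bg_sd, size=n), 0.0, None) if noise.bg_sd > 0 else np.full(n, noise.bg_mean)
        bg_pix_sd = np.maximum(noise.bg_sd, 1.0) * (
            np.exp(rng.normal(0.0, 0.1, size=n)) if noise.bg_sd > 0 else np.ones(n)
        )
        median = noise.gain * np.power(2.0, e) * mult + bg_draw
        processed = np.maximum(median - bg_median, 1.0)
        wab = (median - bg_median) > 2.6 * bg_pix_sd
        frame[f"{prefix}MedianSignal"] = median
        frame[f"{prefix}BGMedianSignal"] = bg_median
        frame[f"{prefix}BGPixSDev"] = bg_pix_sd
        frame[f"{prefix}ProcessedSignal"] = processed
        frame[f"{prefix}IsWellAboveBG"] = wab.astype(int)
        frame[f"{prefix}IsPosAndSignif"] = wab.astype(int)
        frame[f"{prefix}IsFeatNonUnifOL"] = (rng.random(n) < flags.nonunif).astype(int)
        frame[f"{prefix}IsFeatPopnOL"] = (rng.random(n) < flags.popn).astype(int)
        frame[f"{prefix}IsSaturated"] = (rng.random(n) < flags.saturated).astype(int)
    return frame


# ---------------------------------------------------------------------------
# presets: the platform's two validation designs


def _synthetic_probes(rng, n_probes: int) -> list[ProbeRecord]:
    probes = []
    for i in range(1, n_probes + 1):
        seq = _random_seq(rng, 60)
        probes.append(
            ProbeRecord(f"CP{i:06d}", f"gene{i:06d}", f"gene{i:06d}.t1", seq, 0, "designed")
        )
    return probes


def _small_layout(n_probes: int, seed: int) -> ArrayLayout:
    manifest = {"spikein": 30, "stringency": 30, "corner": 40}
    rep_count, rep_copies = 20, 10
    spec = LayoutSpec(
        subarrays=1,
        features_per_subarray=sum(manifest.values()) + rep_count * rep_copies + (n_probes - rep_count),
        control_count=sum(manifest.values()),
        replicate_probe_count=rep_count,
        replicate_copies=rep_copies,
        seed=seed,
        control_manifest=manifest,
    )
    rng = np.random.default_rng(seed)
    return build_layout(_synthetic_probes(rng, n_probes), spec), spec


def _base_expression(rng, layout: ArrayLayout) -> pd.Series:
    sub = layout.subarrays[0]
    ids = pd.Index(pd.unique(sub["feature_id"]))
    base = pd.Series(rng.normal(10.0, 1.5, size=len(ids)), index=ids)
    # stringency/corner controls sit near background
    cls = sub.drop_duplicates("feature_id").set_index("feature_id")["feature_class"]
    base[cls == "corner"] = 2.0
    base[cls == "stringency"] = 8.0
    return base


def preset_selfself(
    n_arrays: int = 3,
    n_probes: int = 5000,
    seed: int = 0,
    spikein_dye_offset: bool = True,
    noise: NoiseModel | None = None,
    flags: FlagRates | None = None,
):
    """Self-self dye-balance design: identical truth in both channels for
    every biological probe; spike-in controls carry their defined inter-dye
    ratios (switch off with ``spikein_dye_offset=False``).

    Returns (layout, truth, scans) with scans a dict array_id -> FE frame.
    """
    layout, _ = _small_layout(n_probes, seed)
    rng = np.random.default_rng(seed + 1)
    base = _base_expression(rng, layout)
    ratios = spikein_expected_ratios()
    spike_ids = [f for f in base.index if str(f).startswith("E1A_")]
    spike_expected = pd.Series(
        {f: ratios[_spikein_level(f) - 1] for f in spike_ids}, dtype=float
    )
    expr = {}
    array_ids = [f"selfself_{i + 1}" for i in range(n_arrays)]
    for aid in array_ids:
        g = base.copy()
        r = base.copy()
        if spikein_dye_offset and spike_ids:
            r[spike_ids] = r[spike_ids] + spike_expected
        expr[(aid, "green")] = g
        expr[(aid, "red")] = r
    truth = SyntheticTruth(expr=expr, spike_expected=spike_expected, seed=seed)
    sim_rng = np.random.default_rng(seed + 2)
    scans = {
        aid: simulate_scan(layout, truth, aid, noise, flags, rng=sim_rng)
        for aid in array_ids
    }
    return layout, truth, scans


def preset_two_isolations(
    n_per_group: int = 8,
    n_probes: int = 5000,
    shifted_probes: int = 12,
    shift_log2: float = 1.23,
    seed: int = 0,
    noise: NoiseModel | None = None,
    flags: FlagRates | None = None,
):
    """Technical-reproducibility design: two RNA isolations, single channel,
    ``n_per_group`` arrays each; exactly ``shifted_probes`` biological probes
    are shifted by ``shift_log2`` in isolation 2.

    Returns (layout, truth, scans, shifted_ids).
    """
    layout, _ = _small_layout(n_probes, seed)
    rng = np.random.default_rng(seed + 1)
    base = _base_expression(rng, layout)
    sub = layout.subarrays[0]
    cls = sub.drop_duplicates("feature_id").set_index("feature_id")["feature_class"]
    bio = [f for f in base.index if cls[f] in ("biological", "replicate")]
    shifted_ids = sorted(rng.choice(bio, size=shifted_probes, replace=False).tolist())
    shifted = pd.Series(shift_log2, index=shifted_ids)

    expr = {}
    array_ids = [f"iso1_{i + 1}" for i in range(n_per_group)] + [
        f"iso2_{i + 1}" for i in range(n_per_group)
    ]
    for aid in array_ids:
        e = base.copy()
        if aid.startswith("iso2"):
            e[shifted_ids] = e[shifted_ids] + shifted
        expr[(aid, "green")] = e
        expr[(aid, "red")] = e  # red unused in the single-channel design
    truth = SyntheticTruth(
        expr=expr, differential={f: shift_log2 for f in shifted_ids}, seed=seed
    )
    sim_rng = np.random.default_rng(seed + 2)
    scans = {
        aid: simulate_scan(layout, truth, aid, noise, flags, rng=sim_rng)
        for aid in array_ids
    }
    return layout, truth, scans, shifted_ids
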