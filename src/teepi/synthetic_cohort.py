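"""Synthetic multi-strain cohort with planted, recorded epigenetic effects.

The generator emulates the study design the pipeline targets: five inbred
strains, three body parts (head, gut, ovary), two histone marks (H3K9me3,
H3K27ac) and three ChIP replicates, with polymorphic TE insertions whose
epigenetic effects on the flanking sequence are planted with known
percentage and spread, and genes whose expression shifts when a linked TE
is present.  Every planted parameter is recorded in :class:`SyntheticTruth`
so downstream effect calls can be scored against ground truth.

Geometry: a single "base" chromosome of random nucleotides is shared by all
strains; each strain's genome is the base sequence with the TE sequences it
carries spliced in.  Per-strain coordinates therefore differ by the
cumulative length of carried TEs upstream of a position, and the generator
records both the carrier-strain TE intervals and the exact junction
position in every non-carrier strain.

Signal model: fold-enrichment bins are i.i.d. lognormal with median 1
(multiplicative noise, matching the ratio scale of fold-change tracks); a
carrier strain with a planted effect has all bins within the planted
spread of the TE span multiplied by (1 + percentage/100) — a boxcar
kernel with a hard edge, so the spread estimator has an unambiguous true
value.  Expression is negative-binomial per gene, with carrier samples of a
linked gene scaled by 2**log2FC in the affected body part.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    BODY_PARTS,
    CARRIER,
    MARKS,
    NON_CARRIER,
    GeneModel,
    GenomicInterval,
    SignalTrack,
    TEInsertion,
    write_fasta,
    write_genes_gff,
    write_signal_track,
)

STRAIN_NAMES = ("AKA", "JUT", "MUN", "SLA", "TOM")
FAMILY_ORDERS = ("LTR", "LINE", "DNA")


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the cohort the pipeline is built for: 5 strains x
    3 body parts x 2 marks x 3 replicates, 200 polymorphic TEs, lognormal
    signal noise with log-sd 0.2, and planted enrichments of +50% spreading
    3 kb from the insertion on a random half of the TEs.
    """

    n_strains: int = 5
    n_te: int = 200
    n_genes: int = 300
    n_families: int = 8
    chrom: str = "2L"
    chrom_length: int | None = None  # derived from spacing when None
    body_parts: tuple[str, ...] = BODY_PARTS
    marks: tuple[str, ...] = MARKS
    replicates: int = 3
    te_length: int = 1000
    # effect mixture
    effect_fraction: float = 0.5          # TEs with any planted effect
    depletion_fraction: float = 0.0       # of affected TEs, fraction depleted
    enrichment_percentage: float = 50.0   # planted % change (enrichment)
    depletion_percentage: float = -40.0   # planted % change (depletion)
    spread_kb: int = 3                    # boxcar half-width in kb
    # noise
    signal_noise_sd: float = 0.2          # sd of log fold-enrichment
    baseline_log_mean: float = 0.0        # log of median fold-enrichment
    nb_dispersion: float = 0.1
    expression_log_mean: float = 4.5      # lognormal mean of gene baselines
    expression_log_sd: float = 1.0
    linked_gene_fraction: float = 0.8     # affected TEs that get a linked gene
    linked_log2fc: float = 1.0            # |log2FC| planted on linked genes
    # window geometry used for TE spacing (isolated placement)
    window_bp: int = 1000
    n_windows_per_side: int = 20
    isolated: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.enrichment_percentage <= -100 or self.depletion_percentage <= -100:
            raise ValueError("planted percentage must be > -100 (signal must stay positive)")
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must lie in [0,1]")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        span = self.n_windows_per_side * self.window_bp
        spacing = (2 * span + self.te_length + 1000) if self.isolated else (
            self.te_length + 2000
        )
        required = span + self.n_te * spacing + span
        if self.chrom_length is None:
            self.chrom_length = required
        elif self.chrom_length < required:
            raise ValueError(
                f"chrom_length {self.chrom_length} too small: need >= {required} "
                f"for {self.n_te} TEs at spacing {spacing}"
            )
        self._spacing = spacing

    @property
    def strains(self) -> tuple[str, ...]:
        base = list(STRAIN_NAMES)
        while len(base) < self.n_strains:
            base.append(f"S{len(base) + 1:02d}")
        return tuple(base[: self.n_strains])


@dataclass
class SyntheticTruth:
    """Planted parameters, recorded for scoring downstream calls.

    ``te_effects[te_id][(body_part, mark)]`` is a (effect, percentage,
    spread_kb) triple and exists only for non-"none" combinations;
    ``breakpoints[(te_id, strain)]`` is the junction position (0-based) in
    each non-carrier strain; ``gene_links[gene_id]`` records the linked TE
    and the signed planted log2 fold-change.
    """

    te_effects: dict[str, dict[tuple[str, str], tuple[str, float, int]]]
    breakpoints: dict[tuple[str, str], int]
    te_base_interval: dict[str, tuple[int, int]]
    gene_links: dict[str, tuple[str, float]]
    signal_noise_sd: float
    nb_dispersion: float

    def effect_of(self, te_id: str, body_part: str, mark: str) -> tuple[str, float, int]:
        return self.te_effects.get(te_id, {}).get((body_part, mark), ("none", 0.0, 0))


@dataclass
class Cohort:
    spec: CohortSpec
    strains: tuple[str, ...]
    chrom: str
    tes: list[TEInsertion]
    genes: list[GeneModel]  # base-coordinate gene models
    truth: SyntheticTruth
    genomes: dict[str, str] = field(default_factory=dict)
    strain_lengths: dict[str, int] = field(default_factory=dict)

    def gene_interval_in_strain(self, gene: GeneModel, strain: str) -> GenomicInterval:
        """Project a base-coordinate gene interval into a strain's coordinates."""
        off = self._offset(strain, gene.interval.start)
        iv = gene.interval
        return GenomicInterval(iv.chrom, iv.start + off, iv.end + off, iv.strand)

    def _offset(self, strain: str, base_pos: int) -> int:
        off = 0
        for te in self.tes:
            if te.presence.get(strain) == CARRIER:
                s, e = self.truth.te_base_interval[te.te_id]
                if s <= base_pos:
                    off += e - s
        return off


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

_NT = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_NT, size=length).tobytes().decode()


def generate_cohort(spec: CohortSpec, with_sequences: bool = True) -> Cohort:
    """Generate strains, TE annotations, genes and planted truth.

    Deterministic under a fixed ``spec.seed``.  When ``with_sequences`` is
    False the nucleotide genomes are skipped (coordinates and truth are
    unchanged); signal and expression simulation do not need them.
    """
    rng = np.random.default_rng(spec.seed)
    strains = spec.strains
    span = spec.n_windows_per_side * spec.window_bp

    # family library: independent random sequences are ~75% divergent
    families = []
    for i in range(spec.n_families):
        families.append(
            (f"fam{i + 1:02d}", FAMILY_ORDERS[i % len(FAMILY_ORDERS)],
             _random_sequence(rng, spec.te_length))
        )

    # base-coordinate TE slots, evenly spaced with jitter
    starts = []
    pos = span + 500
    for _ in range(spec.n_te):
        starts.append(pos + int(rng.integers(0, 500)))
        pos += spec._spacing
    # planted effects
    n_effect = int(round(spec.effect_fraction * spec.n_te))
    effect_ids = set(rng.choice(spec.n_te, size=n_effect, replace=False).tolist())

    tes: list[TEInsertion] = []
    te_effects: dict[str, dict] = {}
    te_base_interval: dict[str, tuple[int, int]] = {}
    conditions = [(bp, mk) for bp in spec.body_parts for mk in spec.marks]
    for i, base_start in enumerate(starts):
        te_id = f"te{i + 1:04d}"
        fam, order, fam_seq = families[int(rng.integers(0, spec.n_families))]
        full = bool(rng.random() < 0.5)
        length = len(fam_seq) if full else max(200, len(fam_seq) // 2)
        n_car = int(rng.integers(1, spec.n_strains))  # 1..n-1 carriers
        carrier_idx = rng.choice(spec.n_strains, size=n_car, replace=False)
        presence = {
            s: (CARRIER if j in carrier_idx else NON_CARRIER)
            for j, s in enumerate(strains)
        }
        te_base_interval[te_id] = (base_start, base_start + length)
        tes.append(
            TEInsertion(
                te_id=te_id,
                family=fam,
                order=order,
                interval={},  # filled after offsets are known
                presence=presence,
                length_class="full-length" if full else "fragment",
                population_frequency=n_car / spec.n_strains,
            )
        )
        if i in effect_ids:
            cond = conditions[int(rng.integers(0, len(conditions)))]
            if rng.random() < spec.depletion_fraction:
                eff = ("depletion", spec.depletion_percentage, spec.spread_kb)
            else:
                eff = ("enrichment", spec.enrichment_percentage, spec.spread_kb)
            te_effects[te_id] = {cond: eff}

    # per-strain coordinates
    breakpoints: dict[tuple[str, str], int] = {}
    for strain in strains:
        off = 0
        for te in tes:
            s, e = te_base_interval[te.te_id]
            if te.presence[strain] == CARRIER:
                te.interval[strain] = GenomicInterval(spec.chrom, s + off, e + off)
                off += e - s
            else:
                breakpoints[(te.te_id, strain)] = s + off

    # genes: linked genes sit just outside the planted spread anchor TE;
    # background genes go midway between TE slots
    genes: list[GeneModel] = []
    gene_links: dict[str, tuple[str, float]] = {}
    affected = [tes[i].te_id for i in sorted(effect_ids)]
    g = 0
    for te_id in affected:
        if rng.random() >= spec.linked_gene_fraction:
            continue
        g += 1
        gid = f"gene{g:04d}"
        s, e = te_base_interval[te_id]
        dist = int(rng.integers(200, max(300, spec.spread_kb * 1000 - 500)))
        gs = e + dist
        genes.append(_make_gene(gid, spec.chrom, gs, rng))
        eff = next(iter(te_effects[te_id].values()))
        sign = -1.0 if (eff[0] == "enrichment") else 1.0
        # repressive-mark enrichment downregulates; active-mark enrichment
        # upregulates; depletion flips the sign
        cond = next(iter(te_effects[te_id].keys()))
        if cond[1] == "H3K27ac":
            sign = -sign
        gene_links[gid] = (te_id, sign * spec.linked_log2fc)
    while g < spec.n_genes:
        g += 1
        gid = f"gene{g:04d}"
        slot = int(rng.integers(0, spec.n_te - 1))
        mid = (starts[slot] + spec.te_length + starts[slot + 1]) // 2
        genes.append(_make_gene(gid, spec.chrom, mid, rng))

    truth = SyntheticTruth(
        te_effects=te_effects,
        breakpoints=breakpoints,
        te_base_interval=te_base_interval,
        gene_links=gene_links,
        signal_noise_sd=spec.signal_noise_sd,
        nb_dispersion=spec.nb_dispersion,
    )

    genomes: dict[str, str] = {}
    strain_lengths: dict[str, int] = {}
    fam_seq_by_id = {f[0]: f[2] for f in families}
    base_seq = _random_sequence(rng, spec.chrom_length) if with_sequences else ""
    for strain in strains:
        extra = sum(
            te_base_interval[te.te_id][1] - te_base_interval[te.te_id][0]
            for te in tes
            if te.presence[strain] == CARRIER
        )
        strain_lengths[strain] = spec.chrom_length + extra
        if with_sequences:
            parts = []
            prev = 0
            for te in tes:
                if te.presence[strain] != CARRIER:
                    continue
                s, e = te_base_interval[te.te_id]
                parts.append(base_seq[prev:s])
                parts.append(fam_seq_by_id[te.family][: e - s])
                prev = s
            parts.append(base_seq[prev:])
            genomes[strain] = "".join(parts)

    return Cohort(
        spec=spec,
        strains=strains,
        chrom=spec.chrom,
        tes=tes,
        genes=genes,
        truth=truth,
        genomes=genomes,
        strain_lengths=strain_lengths,
    )


def _make_gene(gid: str, chrom: str, start: int, rng: np.random.Generator) -> GeneModel:
    """A 2-exon gene with UTRs and an intron, ~2 kb long."""
    strand = "+" if rng.random() < 0.5 else "-"
    utr5 = (start, start + 150)
    cds1 = (start + 150, start + 600)
    intron_end = start + 1100
    cds2 = (intron_end, intron_end + 600)
    utr3 = (intron_end + 600, intron_end + 750)
    iv = GenomicInterval(chrom, start, utr3[1], strand)
    if strand == "+":
        return GeneModel(gid, iv, cds=[cds1, cds2], utr5=[utr5], utr3=[utr3])
    return GeneModel(gid, iv, cds=[cds1, cds2], utr5=[utr3], utr3=[utr5])


# ---------------------------------------------------------------------------
# Signal simulation
# ---------------------------------------------------------------------------

def simulate_signal(
    truth: SyntheticTruth,
    cohort: Cohort,
    bin_bp: int = 10,
    dtype=np.float32,
) -> dict[tuple[str, str, int], SignalTrack]:
    """Simulate fold-enrichment tracks for every strain x condition x replicate.

    Returns a dict keyed by ``(strain, body_part, mark, replicate)``.
    Baseline bins are lognormal with median 1 and log-sd
    ``truth.signal_noise_sd``; carrier strains with a planted effect have
    bins within the planted spread of the TE span multiplied by
    (1 + percentage/100).  Replicates are i.i.d.
    """
    spec = cohort.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    tracks: dict[tuple, SignalTrack] = {}
    for strain in cohort.strains:
        n_bins = -(-cohort.strain_lengths[strain] // bin_bp)
        # multiplier profile per (body_part, mark) for this strain
        for bp in spec.body_parts:
            for mk in spec.marks:
                mult = None
                for te in cohort.tes:
                    if te.presence[strain] != CARRIER:
                        continue
                    eff, pct, spread_kb = truth.effect_of(te.te_id, bp, mk)
                    if eff == "none":
                        continue
                    if pct <= -100:
                        raise ValueError("planted percentage <= -100 gives negative signal")
                    if mult is None:
                        mult = np.ones(n_bins, dtype=np.float64)
                    iv = te.interval[strain]
                    lo = max(0, (iv.start - spread_kb * 1000) // bin_bp)
                    hi = min(n_bins, -(-(iv.end + spread_kb * 1000) // bin_bp))
                    mult[lo:hi] *= 1.0 + pct / 100.0
                for rep in range(1, spec.replicates + 1):
                    vals = rng.lognormal(
                        spec.baseline_log_mean, truth.signal_noise_sd, n_bins
                    )
                    if mult is not None:
                        vals *= mult
                    tracks[(strain, bp, mk, rep)] = SignalTrack(
                        strain, bp, mk, rep,
                        {cohort.chrom: vals.astype(dtype)}, bin_bp,
                    )
    return tracks


def average_replicates(
    tracks: dict[tuple[str, str, str, int], SignalTrack],
) -> dict[tuple[str, str, str], SignalTrack]:
    """Per-bin mean over replicates, ignoring missing bins (all-NaN stays NaN)."""
    grouped: dict[tuple, list[SignalTrack]] = {}
    for (strain, bp, mk, _rep), tr in tracks.items():
        grouped.setdefault((strain, bp, mk), []).append(tr)
    out: dict[tuple, SignalTrack] = {}
    for key, reps in grouped.items():
        chroms = reps[0].values.keys()
        merged = {}
        for chrom in chroms:
            stack = np.stack([r.values[chrom] for r in reps]).astype(np.float64)
            with np.errstate(invalid="ignore"):
                merged[chrom] = np.nanmean(stack, axis=0)
        out[key] = SignalTrack(key[0], key[1], key[2], 0, merged, reps[0].bin_bp)
    return out


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(truth: SyntheticTruth, cohort: Cohort) -> pd.DataFrame:
    """Negative-binomial counts for every gene x (strain, body part, replicate).

    A gene linked to a TE has its mean scaled by 2**log2FC in carrier-strain
    samples of the body part where the TE's effect is planted.  Columns are
    named ``strain_bodypart_rep``.
    """
    spec = cohort.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    carriers = {te.te_id: set(te.carriers) for te in cohort.tes}
    gene_ids = [g.gene_id for g in cohort.genes]
    base_mean = rng.lognormal(
        spec.expression_log_mean, spec.expression_log_sd, len(gene_ids)
    )
    samples = [
        (s, bp, r)
        for s in cohort.strains
        for bp in spec.body_parts
        for r in range(1, spec.replicates + 1)
    ]
    disp = spec.nb_dispersion
    if disp <= 0:
        raise ValueError("dispersion must be positive")
    n_param = 1.0 / disp
    mat = np.empty((len(gene_ids), len(samples)), dtype=np.int64)
    for j, (strain, bp, _rep) in enumerate(samples):
        mean = base_mean.copy()
        for gi, gid in enumerate(gene_ids):
            link = truth.gene_links.get(gid)
            if link is None:
                continue
            te_id, log2fc = link
            eff_conds = truth.te_effects.get(te_id, {})
            affected_bp = {cond[0] for cond in eff_conds}
            if strain in carriers[te_id] and bp in affected_bp:
                mean[gi] = mean[gi] * 2.0 ** log2fc
        p = n_param / (n_param + mean)
        mat[:, j] = rng.negative_binomial(n_param, p)
    cols = [f"{s}_{bp}_{r}" for s, bp, r in samples]
    return pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=cols)


# ---------------------------------------------------------------------------
# On-disk fixture writing
# ---------------------------------------------------------------------------

def write_cohort(
    cohort: Cohort,
    out_dir: str | Path,
    tracks: dict | None = None,
    counts: pd.DataFrame | None = None,
) -> None:
    """Write FASTA/BED/presence/GFF/bedGraph/TSV/JSON fixtures for a cohort."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort.genomes:
        for strain, seq in cohort.genomes.items():
            write_fasta({cohort.chrom: seq}, out / f"{strain}.fa")
    # BED uses each TE's first carrier's coordinates
    with open(out / "tes.bed", "w") as fh:
        for te in cohort.tes:
            strain = te.carriers[0]
            iv = te.interval[strain]
            fh.write(
                "\t".join(
                    map(str, [iv.chrom, iv.start, iv.end, te.te_id, 0, iv.strand,
                              te.family, te.order, te.length_class,
                              te.population_frequency])
                ) + "\n"
            )
    pd.DataFrame.from_dict(
        {te.te_id: te.presence for te in cohort.tes}, orient="index"
    ).rename_axis("te_id").to_csv(out / "presence.tsv", sep="\t")
    write_genes_gff(cohort.genes, out / "genes.gff3")
    if tracks:
        for (strain, bp, mk, rep), tr in tracks.items():
            write_signal_track(tr, out / f"{strain}_{bp}_{mk}_rep{rep}.bedgraph")
    if counts is not None:
        counts.to_csv(out / "counts.tsv", sep="\t")
    payload = {
        "te_effects": {
            te_id: {f"{bp}|{mk}": list(v) for (bp, mk), v in conds.items()}
            for te_id, conds in cohort.truth.te_effects.items()
        },
        "breakpoints": {f"{t}|{s}": p for (t, s), p in cohort.truth.breakpoints.items()},
        "te_base_interval": cohort.truth.te_base_interval,
        "gene_links": cohort.truth.gene_links,
        "spec": {k: v for k, v in dataclasses.asdict(cohort.spec).items()
                 if not isinstance(v, tuple)},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)
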