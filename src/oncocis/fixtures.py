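"""Synthetic input generator for end-to-end runs and tests.

Emulates, at toy scale, every input the annotation pipeline consumes: a
random kilobase-scale genome (FASTA), DHS and histone peak files (BED),
a small handcrafted motif library (JASPAR-style counts), a per-base
conservation track (bedGraph), gene models (BED6), an enhancer-TSS
association table, promoter/enhancer transcript intervals, a mutation
list (TSV) and a gene-by-sample expression matrix with planted outlier
samples. A manifest records the ground truth for every planted mutation.

Default study conditions mirror the cohort the method was demonstrated
on: 17 tumour samples plus 3 normals, a planted expression shift of 8
non-mutant standard deviations for true regulatory mutations, motif
library filtered to mammalian matrices backed by > 20 sites, and
conservation > 0.8 at planted functional bases.

What this generator does NOT emulate: linkage between nearby mutations,
realistic mutational signatures, peak-width distributions from real
ChIP-seq, or expression count noise — passing tests demonstrate the
pipeline's logic, not performance on real tumour genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .motifs import revcomp

__all__ = ["FixtureSpec", "PlantedMutation", "generate_fixtures", "FIXTURE_FILES"]

_BASES = "ACGT"

# The creation/removal motif: an ETS-family-like core. All columns are
# unanimously conserved, so the only qualifying site is the exact
# consensus (or its reverse complement) — which makes planted gain/loss
# events unambiguous.
ETS_CONSENSUS = "CCGGAAGT"

FIXTURE_FILES = {
    "genome": "genome.fa",
    "dhs": "dhs.bed",
    "h3k4me1": "h3k4me1.bed",
    "h3k4me3": "h3k4me3.bed",
    "h3k27ac": "h3k27ac.bed",
    "motifs": "motifs.pfm",
    "conservation": "conservation.bedGraph",
    "genes": "genes.bed",
    "enhancer_tss": "enhancer_tss.tsv",
    "fantom_promoters": "fantom_promoters.bed",
    "fantom_enhancers": "fantom_enhancers.bed",
    "mutations": "mutations.tsv",
    "expression": "expression.tsv",
    "manifest": "manifest.json",
}


@dataclass(frozen=True)
class PlantedMutation:
    """Ground-truth description of one planted mutation.

    ``role`` is one of:

    * ``create``  — in a DHS, conserved, mutation creates the ETS motif,
      expression shifted: should be prioritized;
    * ``remove``  — as above but the wild type carries the motif and the
      mutation destroys it;
    * ``low_conservation`` — in a DHS with a motif change and expression
      shift, but conservation below threshold: must NOT be prioritized;
    * ``background`` — outside any DHS, no engineered motif context.
    """

    pos: int
    sample: str
    role: str
    in_dhs: bool
    conserved: bool
    de_shift_sd: float
    target_gene: Optional[str]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic dataset (defaults = study conditions)."""

    genome_length: int = 100_000
    chrom: str = "chr1"
    n_samples: int = 17
    n_normals: int = 3
    n_background_mutations: int = 30
    n_decoy_dhs: int = 8
    effect_size_sd: float = 8.0
    planted_positive_positions: tuple = (50_000, 72_000)
    low_conservation_position: int = 20_000
    expression_mean: float = 100.0
    expression_sd: float = 10.0

    def validate(self) -> None:
        positions = list(self.planted_positive_positions) + [self.low_conservation_position]
        if len(set(positions)) != len(positions):
            raise ValueError("planted mutation positions must be unique "
                             "(a site cannot satisfy contradictory requirements)")
        for p in positions:
            if not 1_000 <= p <= self.genome_length - 1_000:
                raise ValueError(f"planted position {p} too close to a genome edge")
        if self.n_samples < 4:
            raise ValueError("need at least 4 tumour samples for the t-test")


def _handcrafted_motifs() -> str:
    """Motif library text: the fully conserved ETS-like matrix, a
    partially conserved matrix, a uniform matrix, plus a non-mammalian
    and an under-sampled matrix that the database filter must drop."""
    lines = []

    def record(mid, name, taxon, rows):
        lines.append(f">{mid} {name} taxon={taxon}")
        for base, row in zip("ACGT", rows):
            lines.append(f"{base} [ " + " ".join(str(int(c)) for c in row) + " ]")

    w = len(ETS_CONSENSUS)
    ets = [[0] * w for _ in range(4)]
    for k, b in enumerate(ETS_CONSENSUS):
        ets["ACGT".index(b)][k] = 25
    record("FX0001.1", "ETSX", "mammals", ets)

    # Partially conserved: one column at 84% (conserved), others loose.
    record("FX0002.1", "KLFX", "mammals", [
        [21, 8, 7, 6, 5],
        [2, 7, 6, 7, 8],
        [1, 5, 6, 6, 6],
        [1, 5, 6, 6, 6],
    ])
    # Uniform: scores 0 everywhere, never a hit at cutoff 5.
    record("FX0003.1", "UNIF", "mammals", [[6] * 4, [6] * 4, [6] * 4, [6] * 4])
    # Filtered out by taxon.
    record("FX0004.1", "INSX", "insects", [[25, 0], [0, 25], [0, 0], [0, 0]])
    # Filtered out by site count (20 is not > 20).
    record("FX0005.1", "LOWN", "mammals", [[20, 0, 0], [0, 20, 0], [0, 0, 20], [0, 0, 0]])
    return "\n".join(lines) + "\n"


def _draw_clean_flank(rng: np.random.Generator, length: int) -> str:
    """Random sequence guaranteed free of the ETS consensus on either
    strand (re-drawn deterministically until clean)."""
    rc = revcomp(ETS_CONSENSUS)
    while True:
        seq = "".join(rng.choice(list(_BASES), size=length))
        if ETS_CONSENSUS not in seq and rc not in seq:
            return seq


def generate_fixtures(outdir, seed: int = 7,
                      spec: Optional[FixtureSpec] = None) -> dict:
    """Write the full synthetic input directory; returns the manifest.

    Deterministic: the same seed and spec produce byte-identical files.
    """
    spec = spec or FixtureSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = spec.chrom
    L = spec.genome_length
    samples = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    normals = [f"N{i + 1:02d}" for i in range(spec.n_normals)]

    genome = np.array(list("".join(rng.choice(list(_BASES), size=L))))

    planted: list[PlantedMutation] = []
    mutations: list[tuple[str, int, str, str, str]] = []
    genes = [("GENE1", 10_000, "+"), ("GENE2", 30_000, "-"),
             ("GENE3", 48_000, "+"), ("GENE4", 73_500, "-"),
             ("GENE5", 90_000, "+")]
    targets = {50_000: "GENE3", 72_000: "GENE4",
               spec.low_conservation_position: "GENE2"}

    dhs_rows: list[tuple[int, int]] = []
    me1_rows: list[tuple[int, int]] = []
    me3_rows: list[tuple[int, int]] = []
    ac_rows: list[tuple[int, int]] = []
    cons_runs: list[tuple[int, int, float]] = []  # 0-based half-open

    roles = ["create", "remove"]
    for idx, pos in enumerate(spec.planted_positive_positions):
        role = roles[idx % 2]
        sample = samples[idx % len(samples)]
        ref, alt = _plant_motif_site(genome, rng, pos, role)
        mutations.append((chrom, pos, ref, alt, sample))
        dhs_rows.append((pos - 100, pos + 100))        # center == pos
        me1_rows.append((pos + 200, pos + 400))        # in the right annulus
        ac_rows.append((pos - 400, pos - 200))         # in the left annulus
        cons_runs.append((pos - 6, pos + 5, 0.95))     # mutated base conserved
        cons_runs.append((pos - 21, pos - 6, 0.55))
        cons_runs.append((pos + 5, pos + 20, 0.55))
        planted.append(PlantedMutation(pos, sample, role, True, True,
                                       spec.effect_size_sd, targets[pos]))

    # DHS-resident but poorly conserved: everything else is satisfied, so
    # it isolates the conservation criterion.
    lp = spec.low_conservation_position
    ref, alt = _plant_motif_site(genome, rng, lp, "create")
    mutations.append((chrom, lp, ref, alt, samples[2]))
    dhs_rows.append((lp - 100, lp + 100))
    me1_rows.append((lp + 200, lp + 400))
    cons_runs.append((lp - 21, lp + 20, 0.30))
    planted.append(PlantedMutation(lp, samples[2], "low_conservation", True,
                                   False, spec.effect_size_sd, targets[lp]))

    # Decoy DHS peaks away from planted sites, without histone context.
    guard = [p for p in list(spec.planted_positive_positions) + [lp]]
    for _ in range(spec.n_decoy_dhs):
        while True:
            s = int(rng.integers(500, L - 500))
            if all(abs(s - g) > 1_500 for g in guard):
                break
        dhs_rows.append((s, s + int(rng.integers(120, 300))))
        guard.append(s)

    # Promoter-like context at gene TSSs.
    for name, tss, strand in genes:
        me3_rows.append((tss + 160, tss + 420))

    # Background mutations outside every DHS and planted neighbourhood.
    def in_any_dhs(p1: int) -> bool:
        return any(s < p1 <= e for s, e in dhs_rows)

    for i in range(spec.n_background_mutations):
        while True:
            p1 = int(rng.integers(1_000, L - 1_000))
            if not in_any_dhs(p1) and all(abs(p1 - g) > 700 for g in guard):
                break
        ref = genome[p1 - 1]
        alt = _other_base(rng, ref, avoid=None)
        sample = samples[int(rng.integers(0, len(samples)))]
        mutations.append((chrom, p1, ref, alt, sample))
        cons_runs.append((p1 - 21, p1 + 20, 0.40))
        planted.append(PlantedMutation(p1, sample, "background", False, False,
                                       0.0, None))
        guard.append(p1)

    # ---- write files -------------------------------------------------
    seq = "".join(genome)
    with open(outdir / FIXTURE_FILES["genome"], "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, L, 60):
            fh.write(seq[i:i + 60] + "\n")

    def write_bed(key, rows, names=None):
        with open(outdir / FIXTURE_FILES[key], "w") as fh:
            for i, (s, e) in enumerate(sorted(rows)):
                name = names[i] if names else f"{key}_{i}"
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")

    write_bed("dhs", dhs_rows)
    write_bed("h3k4me1", me1_rows)
    write_bed("h3k4me3", me3_rows)
    write_bed("h3k27ac", ac_rows)

    with open(outdir / FIXTURE_FILES["motifs"], "w") as fh:
        fh.write(_handcrafted_motifs())

    # Merge conservation runs into disjoint records (planted runs never
    # overlap by construction; guard anyway).
    per_base: dict[int, float] = {}
    for s0, e0, score in cons_runs:
        for p1 in range(s0 + 1, e0 + 1):
            if per_base.get(p1, score) != score:
                raise ValueError(f"contradictory conservation at {p1}")
            per_base[p1] = score
    with open(outdir / FIXTURE_FILES["conservation"], "w") as fh:
        for p1 in sorted(per_base):
            fh.write(f"{chrom}\t{p1 - 1}\t{p1}\t{per_base[p1]:.2f}\n")

    with open(outdir / FIXTURE_FILES["genes"], "w") as fh:
        for name, tss, strand in genes:
            start, end = (tss - 1, tss - 1 + 2_000) if strand == "+" else (tss - 2_000, tss)
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")

    with open(outdir / FIXTURE_FILES["enhancer_tss"], "w") as fh:
        for pos, gene in targets.items():
            fh.write(f"{chrom}\t{pos - 100}\t{pos + 100}\t{gene}\n")

    with open(outdir / FIXTURE_FILES["fantom_promoters"], "w") as fh:
        for name, tss, strand in genes:
            fh.write(f"{chrom}\t{max(0, tss - 50)}\t{tss + 50}\t{name}_p\n")
    # Enhancer transcripts deliberately offset from the planted sites so
    # the 500 bp symmetric extension is what produces the overlap.
    with open(outdir / FIXTURE_FILES["fantom_enhancers"], "w") as fh:
        for pos in spec.planted_positive_positions:
            fh.write(f"{chrom}\t{pos + 100}\t{pos + 300}\te_{pos}\n")

    with open(outdir / FIXTURE_FILES["mutations"], "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tsample\n")
        for chrom_, pos, ref, alt, sample in mutations:
            fh.write(f"{chrom_}\t{pos}\t{ref}\t{alt}\t{sample}\n")

    # Expression: per-gene baseline, planted outlier for mutant samples.
    all_samples = samples + normals
    gene_names = [g[0] for g in genes]
    values = {}
    for g in gene_names:
        values[g] = {s: max(0.1, float(rng.normal(spec.expression_mean,
                                                  spec.expression_sd)))
                     for s in all_samples}
    for pm in planted:
        if pm.target_gene and pm.de_shift_sd:
            values[pm.target_gene][pm.sample] = (
                spec.expression_mean + pm.de_shift_sd * spec.expression_sd)
    with open(outdir / FIXTURE_FILES["expression"], "w") as fh:
        fh.write("gene\t" + "\t".join(all_samples) + "\n")
        for g in gene_names:
            fh.write(g + "\t" + "\t".join(f"{values[g][s]:.4f}"
                                          for s in all_samples) + "\n")

    manifest = {
        "seed": seed,
        "chrom": chrom,
        "genome_length": L,
        "samples": samples,
        "normal_samples": normals,
        "effect_size_sd": spec.effect_size_sd,
        "files": dict(FIXTURE_FILES),
        "planted": [
            {"pos": pm.pos, "sample": pm.sample, "role": pm.role,
             "in_dhs": pm.in_dhs, "conserved": pm.conserved,
             "target_gene": pm.target_gene,
             "prioritized": pm.role in ("create", "remove")}
            for pm in planted
        ],
    }
    with open(outdir / FIXTURE_FILES["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _other_base(rng: np.random.Generator, ref: str, avoid) -> str:
    choices = [b for b in _BASES if b != ref and b != avoid]
    return str(rng.choice(choices))


def _plant_motif_site(genome: np.ndarray, rng: np.random.Generator,
                      pos: int, role: str) -> tuple[str, str]:
    """Engineer the neighbourhood of ``pos`` (1-based); return (ref, alt).

    ``create``: the ETS consensus sits with its 4th base (at ``pos``)
    broken, so only the mutant window carries the motif. ``remove``: the
    intact consensus is in the wild type and the substitution at ``pos``
    destroys it. Flanks are re-drawn deterministically until neither the
    wild-type nor the mutant window carries an unintended consensus
    occurrence on either strand.
    """
    rc = revcomp(ETS_CONSENSUS)
    start1 = pos - 3  # consensus spans [pos-3, pos-3+w-1], covering pos
    core_idx = 25 + 3  # index of the mutated base within the stretch
    while True:
        flank_left = _draw_clean_flank(rng, 25)
        flank_right = _draw_clean_flank(rng, 25)
        core = list(ETS_CONSENSUS)
        if role == "create":
            core[3] = _other_base(rng, ETS_CONSENSUS[3], avoid=None)
            ref, alt = core[3], ETS_CONSENSUS[3]
        else:
            ref = ETS_CONSENSUS[3]
            alt = _other_base(rng, ref, avoid=None)
        wt_site = flank_left + "".join(core) + flank_right
        mut_site = wt_site[:core_idx] + alt + wt_site[core_idx + 1:]
        intact, broken = (mut_site, wt_site) if role == "create" else (wt_site, mut_site)
        if (intact.count(ETS_CONSENSUS) == 1 and rc not in intact
                and ETS_CONSENSUS not in broken and rc not in broken):
            break
    s0 = start1 - 1 - 25  # 0-based start of the engineered stretch
    genome[s0:s0 + len(wt_site)] = list(wt_site)
    return ref, alt
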