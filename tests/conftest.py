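import itertools
import math

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from oncocis import PositionWeightMatrix

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")
from oncocis.fixtures import FixtureSpec, generate_fixtures
from oncocis.pipeline import RunConfig


def pwm(name, columns, taxon="mammals"):
    """Build a PWM from per-position (A, C, G, T) count tuples."""
    return PositionWeightMatrix(name=name,
                                counts=np.array(columns, dtype=float).T,
                                taxon=taxon)


def brute_pssm(columns, seq):
    """Independent log-odds scorer working straight off count columns."""
    total = 0.0
    for (a, c, g, t), base in zip(columns, seq):
        counts = {"A": a, "C": c, "G": g, "T": t}
        if base not in counts:
            return float("-inf")
        q = counts[base] / (a + c + g + t)
        if q == 0:
            return float("-inf")
        total += math.log2(q / 0.25)
    return total


def brute_scan(seq, motifs, cutoff=5.0, threshold=0.8):
    """Exhaustive placement x strand enumeration, independent of scan()."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    names = set()
    for motif in motifs:
        cols = [tuple(motif.counts[:, k]) for k in range(motif.width)]
        conserved = []
        for k, col in enumerate(cols):
            tot = sum(col)
            for i, b in enumerate("ACGT"):
                if col[i] / tot > threshold:
                    conserved.append((k, b))
        w = motif.width
        for off in range(len(seq) - w + 1):
            window = seq[off:off + w]
            for oriented in (window,
                             "".join(comp[b] for b in reversed(window))):
                score = brute_pssm(cols, oriented)
                if score > cutoff and all(oriented[k] == b for k, b in conserved):
                    names.add(motif.name)
    return names


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("oncocis_fixtures")
    manifest = generate_fixtures(d, seed=7)
    return d, manifest


@pytest.fixture(scope="session")
def fixture_config(fixture_dir):
    d, manifest = fixture_dir
    cfg = RunConfig.from_paths(
        d / "mutations.tsv", d / "genome.fa", d / "dhs.bed",
        d / "h3k4me1.bed", d / "h3k4me3.bed", d / "h3k27ac.bed",
        d / "motifs.pfm", d / "conservation.bedGraph", d / "genes.bed",
        d / "enhancer_tss.tsv", d / "fantom_promoters.bed",
        d / "fantom_enhancers.bed", d / "expression.tsv",
        manifest["normal_samples"])
    return cfg, manifest
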