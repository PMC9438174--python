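"""Synthetic replicated gene/miRNA time courses with planted structure.

The generator emulates a differentiation time-course array experiment: a
background of non-informative transcripts (per-transcript baseline plus
i.i.d. Gaussian log2 noise), planted gene-miRNA pairs sharing a latent
monotone trajectory with mirrored signs (gene up / miRNA down = Profile 1,
or the reverse = Profile 2), and a matching interaction table carrying the
true pairs plus random decoy edges across confidence classes.  Every stage
of the discovery cascade can therefore be tested, with truth labels,
without downloading any accession.

Defaults mirror the in-house study design: days 0, 2, 4, 6, 8, 15 and 30
with three replicates per day.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, SampleMeta, write_expression
from .interactions import CONFIDENCE_LEVELS, InteractionPair, write_interactions

__all__ = ["PairSpec", "SynthConfig", "TruthTable", "SynthBundle", "generate", "write_fixture", "canonical_config"]

DEFAULT_DAYS = (0.0, 2.0, 4.0, 6.0, 8.0, 15.0, 30.0)
_BASELINE_RANGE = (4.0, 12.0)  # log2 intensity spread typical of arrays


@dataclass(frozen=True)
class PairSpec:
    """One planted gene-miRNA pair sharing a latent trajectory."""

    gene_id: str
    mirna_id: str
    profile: str = "profile1"  # profile1: gene up / miRNA down; profile2: mirror
    amplitude: float = 3.0  # peak log2 excursion of the latent trajectory
    confidence: str = "high"
    shape: str = "exp2"  # exp2 | linear | sigmoid

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.profile not in ("profile1", "profile2"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.shape not in ("exp2", "linear", "sigmoid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"unknown confidence {self.confidence!r}")


@dataclass
class SynthConfig:
    """Study-design parameters of one synthetic experiment (seed mandatory)."""

    seed: int
    days: tuple[float, ...] = DEFAULT_DAYS
    n_replicates: int = 3
    n_background_genes: int = 500
    n_background_mirnas: int = 200
    planted_pairs: tuple[PairSpec, ...] = ()
    noise_sd: float = 0.2  # log2 units, homoscedastic per replicate
    decoy_edges: int = 500
    # planted transcripts sit in the upper half of the intensity range so the
    # declining endpoint of a mirrored pair stays above the detection floor
    # (~10th percentile of a U[4,12] background)
    planted_base_range: tuple[float, float] = (8.5, 11.0)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.days = tuple(float(d) for d in self.days)
        self.planted_pairs = tuple(self.planted_pairs)
        gene_ids = [p.gene_id for p in self.planted_pairs]
        mirna_ids = [p.mirna_id for p in self.planted_pairs]
        if len(set(gene_ids)) != len(gene_ids) or len(set(mirna_ids)) != len(mirna_ids):
            raise ValueError("duplicate transcript ids across planted pair specs")


@dataclass
class TruthTable:
    """Ground truth of a generated bundle: true pairs and per-transcript class labels."""

    true_pairs: list[tuple[str, str]]  # (mirna_id, gene_id)
    labels: dict[str, str]  # transcript id -> background | planted_gene | planted_mirna


@dataclass
class SynthBundle:
    genes: ExpressionDataset
    mirnas: ExpressionDataset
    interactions: list[InteractionPair]
    truth: TruthTable
    config: SynthConfig


def canonical_config(seed: int = 42) -> SynthConfig:
    """The repository's canonical fixture: 10 planted pairs (8 Profile 1 /
    2 Profile 2, alternating confidence high / very_high), 500 background
    genes, 200 background miRNAs, 500 decoy edges, noise 0.2 log2 units."""
    pairs = []
    for i in range(10):
        pairs.append(
            PairSpec(
                gene_id=f"PGENE{i + 1:02d}",
                mirna_id=f"hsa-miR-p{i + 1:02d}",
                profile="profile1" if i < 8 else "profile2",
                amplitude=3.0,
                confidence="high" if i % 2 == 0 else "very_high",
                shape="exp2",
            )
        )
    return SynthConfig(seed=seed, planted_pairs=tuple(pairs))


def _latent(shape: str, days: np.ndarray, amplitude: float) -> np.ndarray:
    """Monotone increasing latent trajectory scaled to [0, amplitude]."""
    s = (days - days[0]) / (days[-1] - days[0])
    if shape == "exp2":
        f = (1.0 - np.exp(-3.0 * s)) / (1.0 - np.exp(-3.0))
    elif shape == "linear":
        f = s
    else:  # sigmoid
        raw = 1.0 / (1.0 + np.exp(-10.0 * (s - 0.5)))
        f = (raw - raw[0]) / (raw[-1] - raw[0])
    return amplitude * f


def generate(config: SynthConfig) -> SynthBundle:
    """Generate the gene/miRNA datasets, interaction table and truth labels.

    Background transcripts: baseline ~ U[4, 12] plus N(0, noise_sd) per
    replicate.  Planted pairs share a latent trajectory f(t) scaled to the
    pair's amplitude: Profile 1 puts gene = base + f + noise and miRNA =
    base - f + noise (Profile 2 mirrored).  Planted baselines are drawn from
    ``planted_base_range`` (upper half of the intensity spread) so both ends
    of the mirrored excursion stay above the detection floor.  Decoy edges
    connect random background
    gene/miRNA pairs with confidences uniform over the four classes.  The
    output is fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.days, dtype=float)
    n_rep = config.n_replicates
    samples = lambda prefix: [
        SampleMeta(f"{prefix}_d{day:g}_r{rep}", day, rep)
        for day in days
        for rep in range(1, n_rep + 1)
    ]
    gene_samples = samples("G")
    mirna_samples = samples("M")
    n_cols = days.size * n_rep
    sample_day = np.repeat(days, n_rep)

    bg_gene_ids = [f"BGENE{i + 1:04d}" for i in range(config.n_background_genes)]
    bg_mirna_ids = [f"hsa-miR-bg{i + 1:04d}" for i in range(config.n_background_mirnas)]
    planted_gene_ids = [p.gene_id for p in config.planted_pairs]
    planted_mirna_ids = [p.mirna_id for p in config.planted_pairs]
    if set(planted_gene_ids) & set(bg_gene_ids) or set(planted_mirna_ids) & set(bg_mirna_ids):
        raise ValueError("planted ids collide with background ids")

    def _background(ids: list[str]) -> np.ndarray:
        base = rng.uniform(*_BASELINE_RANGE, size=len(ids))
        noise = rng.normal(0.0, config.noise_sd, size=(len(ids), n_cols))
        return base[:, None] + noise

    def _planted(spec: PairSpec) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = config.planted_base_range
        gene_base = rng.uniform(lo, hi)
        mirna_base = rng.uniform(lo, hi)
        f = _latent(spec.shape, days, spec.amplitude)
        f_cols = np.repeat(f, n_rep)
        sign = 1.0 if spec.profile == "profile1" else -1.0
        gene_row = gene_base + sign * f_cols + rng.normal(0, config.noise_sd, n_cols)
        mirna_row = mirna_base - sign * f_cols + rng.normal(0, config.noise_sd, n_cols)
        return gene_row, mirna_row

    planted_rows = [_planted(spec) for spec in config.planted_pairs]
    empty = np.empty((0, n_cols))
    gene_values = np.vstack([r[0] for r in planted_rows]) if planted_rows else empty
    mirna_values = np.vstack([r[1] for r in planted_rows]) if planted_rows else empty
    bg_gene_values = _background(bg_gene_ids)
    bg_mirna_values = _background(bg_mirna_ids)

    genes = ExpressionDataset(
        "gene",
        planted_gene_ids + bg_gene_ids,
        np.vstack([gene_values, bg_gene_values]),
        gene_samples,
    )
    mirnas = ExpressionDataset(
        "mirna",
        planted_mirna_ids + bg_mirna_ids,
        np.vstack([mirna_values, bg_mirna_values]),
        mirna_samples,
    )

    # interaction table: true pairs + random decoys among background transcripts
    interactions = [
        InteractionPair(spec.mirna_id, spec.gene_id, spec.confidence, None, "planted")
        for spec in config.planted_pairs
    ]
    if config.decoy_edges > 0:
        if not bg_gene_ids or not bg_mirna_ids:
            raise ValueError("decoy edges require background transcripts")
        seen = {(p.mirna_id, p.gene_id) for p in interactions}
        while len(interactions) < len(config.planted_pairs) + config.decoy_edges:
            m = bg_mirna_ids[rng.integers(len(bg_mirna_ids))]
            g = bg_gene_ids[rng.integers(len(bg_gene_ids))]
            if (m, g) in seen:
                continue
            seen.add((m, g))
            conf = CONFIDENCE_LEVELS[rng.integers(len(CONFIDENCE_LEVELS))]
            interactions.append(InteractionPair(m, g, conf, None, "decoy"))

    labels = {t: "background" for t in bg_gene_ids + bg_mirna_ids}
    labels.update({t: "planted_gene" for t in planted_gene_ids})
    labels.update({t: "planted_mirna" for t in planted_mirna_ids})
    truth = TruthTable(
        true_pairs=[(s.mirna_id, s.gene_id) for s in config.planted_pairs],
        labels=labels,
    )
    return SynthBundle(genes, mirnas, interactions, truth, config)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture(bundle: SynthBundle, out_dir: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write the bundle in the pipeline's input formats plus a manifest JSON.

    The manifest echoes the generating config and carries a SHA-256 per file;
    an existing manifest whose hashes differ from the new content is a
    collision error unless ``overwrite`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_matrix": out / "genes.tsv",
        "gene_meta": out / "genes_meta.tsv",
        "mirna_matrix": out / "mirnas.tsv",
        "mirna_meta": out / "mirnas_meta.tsv",
        "interactions": out / "interactions.tsv",
        "truth": out / "truth.json",
    }
    write_expression(bundle.genes, paths["gene_matrix"], paths["gene_meta"])
    write_expression(bundle.mirnas, paths["mirna_matrix"], paths["mirna_meta"])
    write_interactions(bundle.interactions, paths["interactions"])
    paths["truth"].write_text(
        json.dumps(
            {"true_pairs": bundle.truth.true_pairs, "labels": bundle.truth.labels},
            indent=1,
            sort_keys=True,
        )
    )
    hashes = {name: _sha256(p) for name, p in paths.items()}
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        old = json.loads(manifest_path.read_text())
        if old.get("hashes") != hashes:
            raise FileExistsError(
                f"{manifest_path} exists with different content hashes; "
                "pass overwrite=True to replace"
            )
    config_echo = asdict(bundle.config)
    config_echo["planted_pairs"] = [asdict(p) for p in bundle.config.planted_pairs]
    manifest_path.write_text(json.dumps({"config": config_echo, "hashes": hashes}, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
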