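"""Synthetic expression bundles with planted immune-related lncRNAs,
differential expression and immune subtypes.

The generator uses a latent-factor model: every immune gene set that is
driven by at least one planted lncRNA gets a latent variable; the planted
lncRNA observes that latent plus noise, and each member mRNA of the set
observes a scaled copy of the same latent plus noise.  The scale is chosen so
the population Pearson correlation of each (planted lncRNA, member mRNA)
pair equals the configured ``rho``.  Differential expression is a two-group
mean shift; subtypes are within-pulpitis mean shifts applied to designated
marker sets (and to the lncRNAs driving them, so lncRNA-based clustering can
recover the subtypes).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, resources
from .io import ConfigurationError, ExpressionBundle, GeneSetCollection


@dataclass
class SynthConfig:
    n_normal: int = 5
    n_pulpitis: int = 7
    n_mrna: int = 893
    n_lnc: int = 535
    n_immune_sets: int = 17
    genes_per_set: int = 25
    n_planted_lnc: int = 20
    rho: float = 0.8
    de_frac: float = 0.05
    de_effect: float = 2.0
    noise_sd: float = 0.5
    n_subtypes: int = 2
    subtype_effect: float = 1.5
    baseline: float = 8.0
    dataset: str = "SYNTH"
    seed: int = 0

    def validate(self) -> "SynthConfig":
        counts = {
            "n_normal": self.n_normal, "n_pulpitis": self.n_pulpitis,
            "n_mrna": self.n_mrna, "n_lnc": self.n_lnc,
            "n_immune_sets": self.n_immune_sets,
            "genes_per_set": self.genes_per_set, "n_subtypes": self.n_subtypes,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if self.n_planted_lnc < 0 or self.n_planted_lnc > self.n_lnc:
            raise ConfigurationError("n_planted_lnc must lie in [0, n_lnc]")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError("rho must lie in [0, 1)")
        if not 0.0 <= self.de_frac <= 1.0:
            raise ConfigurationError("de_frac must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.genes_per_set * self.n_immune_sets > self.n_mrna:
            raise ConfigurationError(
                "set sizes exceed gene pool: genes_per_set * n_immune_sets "
                f"= {self.genes_per_set * self.n_immune_sets} > n_mrna = {self.n_mrna}"
            )
        if self.noise_sd > 0 and self.rho > 0:
            if self.rho ** 2 * (1 + self.noise_sd ** 2) >= 1.0:
                raise ConfigurationError(
                    "infeasible (rho, noise_sd): rho^2 * (1 + noise_sd^2) must be < 1"
                )
        return self


@dataclass
class GroundTruth:
    planted_lnc_ids: set[str]
    lnc_to_set: dict[str, str]
    de_gene_ids: set[str]
    subtype_labels: dict[str, int]
    subtype_marker_sets: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_lnc_ids": sorted(self.planted_lnc_ids),
            "lnc_to_set": self.lnc_to_set,
            "de_gene_ids": sorted(self.de_gene_ids),
            "subtype_labels": self.subtype_labels,
            "subtype_marker_sets": self.subtype_marker_sets,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_lnc_ids=set(payload["planted_lnc_ids"]),
            lnc_to_set=dict(payload["lnc_to_set"]),
            de_gene_ids=set(payload["de_gene_ids"]),
            subtype_labels={k: int(v) for k, v in payload["subtype_labels"].items()},
            subtype_marker_sets={k: int(v) for k, v in payload.get("subtype_marker_sets", {}).items()},
        )


def _member_loading(rho: float, noise_sd: float) -> float:
    """Latent-factor loading giving population Pearson correlation rho between
    lncRNA = latent + e and mRNA = a * latent + e'."""
    if rho == 0:
        return 0.0
    if noise_sd == 0:
        return 1.0
    c = rho ** 2 * (1 + noise_sd ** 2)
    return noise_sd * math.sqrt(c / (1 - c))


def _set_names(n: int) -> list[str]:
    canonical = resources.load_immune_sets().names()
    if n <= len(canonical):
        return canonical[:n]
    width = len(str(n))
    return canonical + [f"IMMUNE_SET_{i + 1:0{width}d}" for i in range(len(canonical), n)]


def generate_bundle(
    config: SynthConfig, truth: GroundTruth | None = None
) -> tuple[ExpressionBundle, GeneSetCollection, GroundTruth]:
    """Generate a bundle, its immune gene-set collection and ground truth.

    Passing an existing *truth* reuses its planted-lncRNA assignment and DE
    gene choice while drawing fresh noise (replicate bundles from the same
    structure, e.g. for cross-dataset agreement checks).  Output is
    byte-identical for identical inputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    normal = [f"N{i + 1:02d}" for i in range(config.n_normal)]
    pulpitis = [f"P{i + 1:02d}" for i in range(config.n_pulpitis)]
    samples = normal + pulpitis
    n_samples = len(samples)
    is_pulpitis = np.array([s in set(pulpitis) for s in samples])

    mrna_ids = [f"M{i + 1:05d}" for i in range(config.n_mrna)]
    lnc_ids = [f"L{i + 1:04d}" for i in range(config.n_lnc)]
    set_names = _set_names(config.n_immune_sets)
    members = {
        set_names[k]: mrna_ids[k * config.genes_per_set:(k + 1) * config.genes_per_set]
        for k in range(config.n_immune_sets)
    }
    sets = GeneSetCollection(
        sets={name: frozenset(genes) for name, genes in members.items()},
        category={name: name for name in set_names},
        provenance=f"synthetic (seed={config.seed})",
    )

    # --- structural choices (reused when truth is given) -------------------
    if truth is None:
        planted = lnc_ids[: config.n_planted_lnc]
        lnc_to_set = {
            lid: set_names[i % config.n_immune_sets] for i, lid in enumerate(planted)
        }
        n_de_m = int(round(config.de_frac * config.n_mrna))
        n_de_l = int(round(config.de_frac * config.n_lnc))
        de_genes = set(rng.choice(mrna_ids, size=n_de_m, replace=False)) | set(
            rng.choice(lnc_ids, size=n_de_l, replace=False)
        )
    else:
        if not truth.planted_lnc_ids <= set(lnc_ids):
            raise ConfigurationError("truth planted lncRNAs not in this config's id space")
        planted = sorted(truth.planted_lnc_ids)
        lnc_to_set = dict(truth.lnc_to_set)
        de_genes = set(truth.de_gene_ids)
        # keep the RNG call sequence aligned with the fresh-truth branch
        rng.choice(mrna_ids, size=int(round(config.de_frac * config.n_mrna)), replace=False)
        rng.choice(lnc_ids, size=int(round(config.de_frac * config.n_lnc)), replace=False)

    subtype_labels = {s: i % config.n_subtypes for i, s in enumerate(pulpitis)}
    marker_sets = {
        set_names[s]: s for s in range(min(config.n_subtypes, config.n_immune_sets))
    }

    # --- expression --------------------------------------------------------
    de_sign = {g: 1.0 if rng.random() < 0.5 else -1.0 for g in sorted(de_genes)}
    driven = sorted({lnc_to_set[l] for l in planted})
    # latent realizations are standardized across samples (fixed-effects
    # latent): the planted correlation then concentrates near rho even at
    # small n instead of inheriting the latent's realized-norm variability
    latents = {}
    for name in driven:
        u = rng.standard_normal(n_samples)
        if n_samples > 1 and u.std() > 0:
            u = (u - u.mean()) / u.std()
        latents[name] = u
    a = _member_loading(config.rho, config.noise_sd)

    mrna = config.baseline + rng.normal(0.0, config.noise_sd, (config.n_mrna, n_samples))
    lnc = config.baseline + rng.normal(0.0, config.noise_sd, (config.n_lnc, n_samples))
    mrna_pos = {g: i for i, g in enumerate(mrna_ids)}
    lnc_pos = {g: i for i, g in enumerate(lnc_ids)}

    def _shaped_noise(raw: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Orthogonalize a noise row against the latent and rescale to
        noise_sd, so realized planted correlations concentrate at rho
        instead of inheriting small-n noise/latent alignment."""
        e = raw - raw.mean()
        uu = float(u @ u)
        if uu > 0:
            e = e - (e @ u) / uu * u
        sd = e.std()
        return e / sd * config.noise_sd if sd > 0 else e

    for set_name in driven:
        u = latents[set_name]
        for g in members[set_name]:
            row = mrna_pos[g]
            noise = mrna[row, :] - config.baseline
            mrna[row, :] = config.baseline + a * u + _shaped_noise(noise, u)
    for lid in planted:
        u = latents[lnc_to_set[lid]]
        row = lnc_pos[lid]
        noise = lnc[row, :] - config.baseline
        lnc[row, :] = config.baseline + u + _shaped_noise(noise, u)

    for g, sign in de_sign.items():
        row = (mrna, mrna_pos[g]) if g in mrna_pos else (lnc, lnc_pos[g])
        row[0][row[1], is_pulpitis] += sign * config.de_effect

    # subtype shifts: marker-set members and their driving lncRNAs
    subtype_of = np.array([subtype_labels.get(s, -1) for s in samples])
    for set_name, s in marker_sets.items():
        mask = subtype_of == s
        rows = [mrna_pos[g] for g in members[set_name]]
        mrna[np.ix_(rows, np.where(mask)[0])] += config.subtype_effect
        driver_rows = [lnc_pos[l] for l in planted if lnc_to_set[l] == set_name]
        if driver_rows:
            lnc[np.ix_(driver_rows, np.where(mask)[0])] += config.subtype_effect

    design = pd.DataFrame(
        {
            "condition": ["normal"] * config.n_normal + ["pulpitis"] * config.n_pulpitis,
            "dataset": config.dataset,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    bundle = ExpressionBundle(
        lnc=pd.DataFrame(lnc, index=lnc_ids, columns=samples),
        mrna=pd.DataFrame(mrna, index=mrna_ids, columns=samples),
        design=design,
    ).validate()
    out_truth = GroundTruth(
        planted_lnc_ids=set(planted),
        lnc_to_set=lnc_to_set,
        de_gene_ids=de_genes,
        subtype_labels=subtype_labels,
        subtype_marker_sets=marker_sets,
    )
    return bundle, sets, out_truth


FIXTURE_FILES = (
    "lnc_expression.tsv",
    "mrna_expression.tsv",
    "design.tsv",
    "immune_sets.gmt",
    "ground_truth.json",
)


def write_fixture(
    bundle: ExpressionBundle,
    sets: GeneSetCollection,
    truth: GroundTruth,
    dir_path: str | Path,
) -> list[Path]:
    """Write the five fixture files and return their paths (the manifest)."""
    out = Path(dir_path)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = [out / name for name in FIXTURE_FILES]
        io.write_matrix(bundle.lnc, paths[0])
        io.write_matrix(bundle.mrna, paths[1])
        io.write_design(bundle.design, paths[2])
        io.write_gmt(sets, paths[3])
        truth.to_json(paths[4])
    except OSError as exc:
        raise io.PipelineError(f"failed writing fixture under {out}: {exc}") from exc
    return paths


def read_fixture(dir_path: str | Path) -> tuple[ExpressionBundle, GeneSetCollection, GroundTruth]:
    out = Path(dir_path)
    bundle = io.read_bundle(out / FIXTURE_FILES[0], out / FIXTURE_FILES[1], out / FIXTURE_FILES[2])
    sets = io.read_gmt(out / FIXTURE_FILES[3])
    truth = GroundTruth.from_json(out / FIXTURE_FILES[4])
    return bundle, sets, truth


def gse92681_like_config(**overrides) -> SynthConfig:
    """Scaled-down bundle shaped like the 5-normal / 7-pulpitis cohort."""
    defaults = dict(n_normal=5, n_pulpitis=7, dataset="GSE92681-like", seed=92681)
    defaults.update(overrides)
    return SynthConfig(**defaults).validate()


def gse77459_like_config(**overrides) -> SynthConfig:
    """Scaled-down bundle shaped like the 6-normal / 6-pulpitis cohort."""
    defaults = dict(n_normal=6, n_pulpitis=6, dataset="GSE77459-like", seed=77459)
    defaults.update(overrides)
    return SynthConfig(**defaults).validate()


def config_to_dict(config: SynthConfig) -> dict:
    return asdict(config)
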