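"""Synthetic fullerene-derivative benchmark generator.

The real study data — 169 derivatives, 27 descriptors, Bscores against
1117 proteins — is emulated by a small latent-factor model with known
ground truth, so every pipeline stage can be tested end to end:

* a *size* latent drives the mutually correlated bulk descriptors
  (polarizability QPpolrz, topological diameter TD, total surface area,
  molecular weight, non-H atoms, rotatable bonds);
* an *aromaticity* latent drives the aromatic block and, with opposite
  sign, the sp3-atoms / stereo-centers block, with per-column noise
  calibrated so the realized aromatic-vs-sp3 correlation matches the
  configured target (default -0.85);
* a *polarity* latent drives the H-bonding / PSA block and, negatively,
  cLogP;
* Bscores are a noisy affine function of the size latent with per-cluster
  offsets and gains for ``protein_clusters`` groups of proteins, mapped
  onto the ~3900-8000 score range.

Count-like descriptors are rounded to non-negative integers after noise
is added.  Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "SynthConfig",
    "SynthDataset",
    "DESCRIPTOR_NAMES",
    "generate_descriptors",
    "generate_bindings",
    "generate_dataset",
    "generate_clustered_profiles",
]

# (latent, sign, scale, offset, count_like) per descriptor column.  The
# 25 drug-like names plus QPpolrz and TD mirror a DataWarrior-style
# descriptor panel for fullerene derivatives.
_DESCRIPTOR_FACTORS: dict[str, tuple[str, float, float, float, bool]] = {
    "QPpolrz": ("size", +1, 80.0, 60.0, False),
    "TD": ("size", +1, 20.0, 8.0, True),
    "total surface area": ("size", +1, 600.0, 300.0, False),
    "Mol_weight": ("size", +1, 900.0, 720.0, False),
    "non-H atoms": ("size", +1, 60.0, 60.0, True),
    "rotatable bonds": ("size", +1, 30.0, 0.0, True),
    "ring closures": ("size", +1, 4.0, 31.0, True),
    "small rings": ("size", +1, 8.0, 1.0, True),
    "aromatic atoms": ("aromatic", +1, 40.0, 0.0, True),
    "aromatic rings": ("aromatic", +1, 7.0, 0.0, True),
    "aromatic nitrogen": ("aromatic", +1, 4.0, 0.0, True),
    "sp3-atoms": ("aromatic", -1, 90.0, 90.0, True),
    "stereo centers": ("aromatic", -1, 30.0, 30.0, True),
    "H-acceptors": ("polarity", +1, 20.0, 0.0, True),
    "H-donors": ("polarity", +1, 10.0, 0.0, True),
    "relative PSA": ("polarity", +1, 0.6, 0.0, False),
    "polar surface area": ("polarity", +1, 300.0, 0.0, False),
    "electronegative atoms": ("polarity", +1, 25.0, 3.0, True),
    "non-C/H atoms": ("polarity", +1, 28.0, 3.0, True),
    "amides": ("polarity", +1, 5.0, 0.0, True),
    "amines": ("polarity", +1, 6.0, 0.0, True),
    "basic nitrogen": ("polarity", +1, 6.0, 0.0, True),
    "acidic oxygens": ("polarity", +1, 8.0, 0.0, True),
    "cLogP": ("polarity", -1, 6.0, 12.0, False),
    "cLogS": ("polarity", +1, 6.0, -10.0, False),
    "drug-likeness": ("independent", +1, 4.0, -2.0, False),
    "symmetric atoms": ("independent", +1, 20.0, 0.0, True),
}

DESCRIPTOR_NAMES: list[str] = list(_DESCRIPTOR_FACTORS)

# Descriptor pair whose realized cross-correlation is calibrated.
_AROMATIC_BLOCK = {"aromatic atoms", "aromatic rings", "aromatic nitrogen"}
_SP3_BLOCK = {"sp3-atoms", "stereo centers"}

_LATENT_VAR = 1.0 / 12.0  # variance of a Uniform(0, 1) latent


@dataclass(frozen=True)
class SynthConfig:
    """Study-shaped generator settings.

    Defaults mirror the real dataset: 169 compounds, 27 descriptors,
    a protein panel (200 by default; 1117 at full scale) in 5 response
    clusters, Bscores spanning roughly 3900-8000.
    """

    n_compounds: int = 169
    n_descriptors: int = 27
    n_proteins: int = 200
    protein_clusters: int = 5
    noise_sd: float = 0.05
    aromatic_sp3_cc: float = -0.85
    bscore_offset: float = 3900.0
    bscore_gain: float = 4000.0
    plausible_range: tuple[float, float] = (3600.0, 8400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 2 or self.n_descriptors < 2 or self.n_proteins < 2:
            raise InputError("n_compounds, n_descriptors and n_proteins must be >= 2")
        if self.n_descriptors > len(DESCRIPTOR_NAMES):
            raise InputError(
                f"at most {len(DESCRIPTOR_NAMES)} named descriptors are available"
            )
        if self.protein_clusters < 1 or self.protein_clusters > self.n_proteins:
            raise InputError("protein_clusters must lie in 1..n_proteins")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        if not (-1.0 < self.aromatic_sp3_cc < 0.0):
            raise InputError("aromatic_sp3_cc must lie in (-1, 0)")
        if self.bscore_gain <= 0:
            raise InputError("bscore_gain must be positive")

    @property
    def descriptor_names(self) -> list[str]:
        return DESCRIPTOR_NAMES[: self.n_descriptors]

    def aromatic_noise_sd(self) -> float:
        """Per-column latent-scale noise giving the target aromatic/sp3 CC.

        Two columns sharing a Uniform latent with independent noise of
        sd ``n`` correlate at var / (var + n^2); solving for the target
        magnitude gives n.  Zero overall noise disables this too.
        """
        if self.noise_sd == 0:
            return 0.0
        target = abs(self.aromatic_sp3_cc)
        return float(np.sqrt(_LATENT_VAR * (1.0 / target - 1.0)))


@dataclass
class SynthDataset:
    """Generated benchmark with full ground truth."""

    X: pd.DataFrame  # compounds x descriptors, raw (unnormalized) units
    B: pd.DataFrame  # compounds x proteins Bscores
    latents: pd.DataFrame  # compounds x (size, aromaticity, polarity)
    protein_clusters: pd.Series  # protein id -> cluster index
    protein_params: pd.DataFrame  # per-protein offset and gain
    cluster_params: pd.DataFrame  # per-cluster offset and gain
    range_violations: int  # Bscore cells outside the plausible range
    config: SynthConfig


def _compound_ids(n: int) -> list[str]:
    return [f"FD{k + 1:03d}" for k in range(n)]


def _protein_ids(n: int) -> list[str]:
    return [f"P{k + 1:04d}" for k in range(n)]


def generate_descriptors(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the descriptor table and its ground-truth latents."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_compounds
    latents = pd.DataFrame(
        {
            "size": rng.random(n),
            "aromaticity": rng.random(n),
            "polarity": rng.random(n),
        },
        index=_compound_ids(n),
    )
    arom_sd = config.aromatic_noise_sd()
    cols = {}
    for name in config.descriptor_names:
        latent_key, sign, scale, offset, count_like = _DESCRIPTOR_FACTORS[name]
        if latent_key == "size":
            base = latents["size"].to_numpy()
        elif latent_key == "aromatic":
            base = latents["aromaticity"].to_numpy()
        elif latent_key == "polarity":
            base = latents["polarity"].to_numpy()
        else:  # independent filler column
            base = rng.random(n)
        sd = arom_sd if name in (_AROMATIC_BLOCK | _SP3_BLOCK) else config.noise_sd
        noise = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        values = offset + sign * scale * base + scale * noise
        if count_like:
            values = np.clip(np.rint(values), 0, None)
        cols[name] = values
    X = pd.DataFrame(cols, index=latents.index)
    return X, latents


def _cluster_params(config: SynthConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evenly spread cluster responses (weaker-to-stronger binders)."""
    k = config.protein_clusters
    rel = np.arange(k) / max(k - 1, 1)
    cluster_offset = config.bscore_offset + 200.0 * rel
    cluster_gain = config.bscore_gain * (0.50 + 0.40 * rel)
    assignment = np.sort(np.arange(config.n_proteins) % k)
    return cluster_offset, cluster_gain, assignment


def _draw_protein_params(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    cluster_offset, cluster_gain, assignment = _cluster_params(config)
    offset = cluster_offset[assignment] + rng.normal(0, 25.0, config.n_proteins)
    gain = cluster_gain[assignment] + rng.normal(
        0, 0.01 * config.bscore_gain, config.n_proteins
    )
    return offset, gain


def generate_bindings(config: SynthConfig, latents: pd.DataFrame) -> pd.DataFrame:
    """Draw the Bscore matrix from the size latent with protein clusters.

    Protein p in cluster c scores offset_c + gain_c * size + noise, with
    small per-protein jitter on offset and gain so profiles cluster.
    Out-of-range values are left as drawn; callers can count them via
    :func:`generate_dataset`.
    """
    if "size" not in latents.columns or len(latents) != config.n_compounds:
        raise InputError("latents do not match the configuration they came from")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    protein_offset, protein_gain = _draw_protein_params(config, rng)
    s = latents["size"].to_numpy()
    noise = rng.normal(
        0.0, config.noise_sd * config.bscore_gain, (config.n_compounds, config.n_proteins)
    )
    values = protein_offset[None, :] + np.outer(s, protein_gain) + noise
    return pd.DataFrame(values, index=latents.index, columns=_protein_ids(config.n_proteins))


def generate_clustered_profiles(
    n_clusters: int = 4,
    members_per_cluster: int = 3,
    n_features: int = 40,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Well-separated object profiles in [0, 1] for map-occupancy studies.

    Each cluster gets a random binary-ish prototype profile; members are
    the prototype plus Gaussian jitter.  Returns the objects x features
    table and the ground-truth cluster labels.
    """
    if n_clusters < 1 or members_per_cluster < 1 or n_features < 1:
        raise InputError("cluster layout parameters must be positive")
    rng = np.random.default_rng(seed)
    prototypes = rng.integers(0, 2, size=(n_clusters, n_features)) * 0.8 + 0.1
    rows, labels, ids = [], [], []
    for c in range(n_clusters):
        for m in range(members_per_cluster):
            rows.append(
                np.clip(prototypes[c] + rng.normal(0, noise_sd, n_features), 0, 1)
            )
            labels.append(c)
            ids.append(f"obj_{c}_{m}")
    profiles = pd.DataFrame(rows, index=ids)
    return profiles, pd.Series(labels, index=ids, name="cluster")


def generate_dataset(config: SynthConfig, write_dir: str | Path | None = None) -> SynthDataset:
    """Compose descriptors and bindings; optionally write TSV fixtures."""
    X, latents = generate_descriptors(config)
    B = generate_bindings(config, latents)
    cluster_offset, cluster_gain, assignment = _cluster_params(config)
    # Same stream position as generate_bindings, so the recorded
    # per-protein parameters are exactly the ones used for B.
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    protein_offset, protein_gain = _draw_protein_params(config, rng)
    lo, hi = config.plausible_range
    dataset = SynthDataset(
        X=X,
        B=B,
        latents=latents,
        protein_clusters=pd.Series(assignment, index=B.columns, name="cluster"),
        protein_params=pd.DataFrame(
            {"offset": protein_offset, "gain": protein_gain}, index=B.columns
        ),
        cluster_params=pd.DataFrame(
            {"offset": cluster_offset, "gain": cluster_gain}
        ),
        range_violations=int(((B.values < lo) | (B.values > hi)).sum()),
        config=config,
    )
    if write_dir is not None:
        out = Path(write_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            paths = {
                "descriptors": out / "descriptors.tsv",
                "bscores": out / "bscores.tsv",
                "latents": out / "latents.tsv",
                "protein_clusters": out / "protein_clusters.tsv",
            }
            X.to_csv(paths["descriptors"], sep="\t")
            B.to_csv(paths["bscores"], sep="\t")
            latents.to_csv(paths["latents"], sep="\t")
            dataset.protein_clusters.to_csv(paths["protein_clusters"], sep="\t")
            manifest = {
                "config": asdict(config),
                "seed": config.seed,
                "range_violations": dataset.range_violations,
                "checksums": {
                    name: hashlib.sha256(path.read_bytes()).hexdigest()
                    for name, path in paths.items()
                },
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        except OSError as exc:
            raise InputError(f"cannot write fixtures under {out}: {exc}") from exc
    return dataset
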