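"""Synthetic multi-plex PSM generator with full ground truth.

The generator emulates the benchmark designs commonly used to validate
isobaric quantification software:

* a single-cell carrier design (``ds1_carrier``): one high-abundance carrier
  channel (14-434 x a single-cell channel), one empty channel next to it,
  and isotopic impurity leakage that inflates the carrier's neighbors;
* a two-proteome ratio series (``ds3_two_proteome``): constant human
  background with yeast spiked at 1, 1.75, 3, 5.2 and 9 units against a
  3.9-unit reference channel, replicated over plexes with per-plex batch
  scale factors;
* a two-species ratio-compression design (``ds5_phospho_ratios``):
  human:yeast at 100:0 / 100:6 / 100:9 / 100:12 in triplicate with empty
  channels and per-PSM co-isolation contamination that sets the true PIF.

Forward model per PSM: protein abundance is lognormal per species; the true
channel intensity is abundance x per-sample mixing amount x per-plex batch
factor; co-isolation adds ``f/(1-f)`` of a background-proteome reporter
pattern and sets the PSM's PIF to ``1-f``; isotopic impurities mix channels
via ``y = A.T x``; multiplicative lognormal noise is applied per channel.
Everything is reconstructable from the returned ground truth, and a fixed
seed reproduces the tables exactly.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .label_model import (
    CorrectionFactors,
    LabelSet,
    build_mixing_matrix,
    load_label_set,
)
from .quant import ExperimentalDesign, PSMTable, META_COLUMNS

__all__ = [
    "SpeciesSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_plexes",
    "expected_observed",
    "load_sim_config",
    "get_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = ("ds1_carrier", "ds3_two_proteome", "ds5_phospho_ratios")


@dataclass(frozen=True)
class SpeciesSpec:
    """One proteome in the mixture design.

    ``condition_amounts`` maps condition label -> mixing amount (arbitrary
    mass units) of this species in a sample channel of that condition;
    ``reference_amount`` and ``carrier_amount`` are its amounts in reference
    and carrier channels.
    """

    name: str
    n_proteins: int
    condition_amounts: Mapping[str, float]
    reference_amount: float = 0.0
    carrier_amount: float = 0.0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if any(a < 0 for a in self.condition_amounts.values()):
            raise ValueError("mixing amounts must be >= 0")
        if self.reference_amount < 0 or self.carrier_amount < 0:
            raise ValueError("mixing amounts must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated multi-plex experiment."""

    label_set: LabelSet
    channel_roles: tuple[str, ...]
    channel_conditions: tuple[str | None, ...]
    species: tuple[SpeciesSpec, ...]
    n_plexes: int = 1
    psms_per_protein: float = 5.0  # Poisson mean per protein per plex
    batch_factors: tuple[float, ...] | None = None
    batch_factor_range: tuple[float, float] | None = None
    noise_sigma: float = 0.1  # lognormal sigma, natural-log units
    contamination_clean_fraction: float = 1.0  # P(f == 0)
    contamination_max: float = 0.0  # else f ~ Uniform(0, max)
    background_species: str | None = None
    correction_factors: CorrectionFactors | None = None
    abundance_sigma: float = 2.0  # lognormal sigma of protein abundances
    precursor_mu: float = float(np.log(1e6))
    precursor_sigma: float = 1.0
    fill_time_range: tuple[float, float] = (5.0, 50.0)
    empty_noise_floor: float = 0.0
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        n = self.label_set.n
        if len(self.channel_roles) != n or len(self.channel_conditions) != n:
            raise ValueError("channel role/condition lists must match the label-set size")
        for role, cond in zip(self.channel_roles, self.channel_conditions):
            if role == "sample" and not cond:
                raise ValueError("every sample channel needs a condition label")
        if self.n_plexes < 1:
            raise ValueError("need at least one plex")
        if self.batch_factors is not None:
            if len(self.batch_factors) != self.n_plexes:
                raise ValueError("one batch factor per plex required")
            if any(b <= 0 for b in self.batch_factors):
                raise ValueError("batch factors must be > 0")
        if self.noise_sigma < 0 or self.abundance_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if not 0.0 <= self.contamination_clean_fraction <= 1.0:
            raise ValueError("contamination_clean_fraction must be in [0, 1]")
        if not 0.0 <= self.contamination_max < 1.0:
            raise ValueError("contamination_max must be in [0, 1)")
        if self.contamination_max > 0 and self.background_species is None:
            raise ValueError("contamination requires a background_species")
        if self.background_species is not None and self.background_species not in {
            s.name for s in self.species
        }:
            raise ValueError(f"background species {self.background_species!r} not in species list")
        conditions = {c for c in self.channel_conditions if c}
        for sp in self.species:
            missing = conditions - set(sp.condition_amounts)
            if missing:
                raise ValueError(f"species {sp.name!r} lacks amounts for conditions {sorted(missing)}")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(c for c in self.channel_conditions if c))


@dataclass
class GroundTruth:
    """Everything needed to reconstruct expected observed intensities.

    ``true_clean`` holds the batch-scaled, contamination-free channel
    intensities of each PSM; ``true_preleak`` additionally includes the
    co-isolation contribution but not yet the impurity mixing.
    """

    proteins: pd.DataFrame  # protein_id, species, abundance
    sample_info: pd.DataFrame  # sample, plex, condition, group
    condition_amounts: pd.DataFrame  # species x condition
    reference_amounts: dict[str, float]
    batch_factors: dict
    psm: pd.DataFrame  # psm_id, protein_id, species, plex, true_pif
    true_clean: np.ndarray
    true_preleak: np.ndarray

    def true_log2_ratio_to_reference(self, species: str, condition: str) -> float:
        amount = float(self.condition_amounts.loc[species, condition])
        ref = self.reference_amounts[species]
        if amount <= 0 or ref <= 0:
            raise ValueError("log2 ratio undefined for zero amounts")
        return float(np.log2(amount / ref))

    def true_log2_ratio_to_sample_sum(self, species: str, condition: str) -> float:
        """Expected ratio of one sample channel to the within-plex sample sum."""
        amounts = self.condition_amounts.loc[species]
        per_channel = [
            amounts[c]
            for c, ok in zip(self.sample_info["condition"], self.sample_info["in_first_plex"])
            if ok
        ]
        total = float(np.sum(per_channel))
        amount = float(amounts[condition])
        if amount <= 0 or total <= 0:
            raise ValueError("log2 ratio undefined for zero amounts")
        return float(np.log2(amount / total))


def _channel_profile(cfg: SimConfig, sp: SpeciesSpec) -> np.ndarray:
    """Per-channel mixing amount of one species (before abundance and batch)."""
    prof = np.zeros(cfg.label_set.n)
    for i, (role, cond) in enumerate(zip(cfg.channel_roles, cfg.channel_conditions)):
        if role == "sample":
            prof[i] = sp.condition_amounts[cond]
        elif role == "reference":
            prof[i] = sp.reference_amount
        elif role == "carrier":
            prof[i] = sp.carrier_amount
    return prof


def _build_design(cfg: SimConfig) -> tuple[ExperimentalDesign, pd.DataFrame]:
    rows = []
    sample_rows = []
    for p in range(cfg.n_plexes):
        plex = f"plex{p + 1}"
        rep_counter: dict[str, int] = {}
        for ch, role, cond in zip(cfg.label_set.channels, cfg.channel_roles, cfg.channel_conditions):
            sample = group = None
            if role == "sample":
                rep_counter[cond] = rep_counter.get(cond, 0) + 1
                sample = f"{plex}.{cond}.r{rep_counter[cond]}"
                group = cond
                sample_rows.append(
                    {
                        "sample": sample,
                        "plex": plex,
                        "condition": cond,
                        "group": cond,
                        "in_first_plex": p == 0,
                    }
                )
            rows.append({"plex": plex, "channel": ch, "role": role, "sample": sample, "group": group})
    design = ExperimentalDesign(label_set=cfg.label_set, table=pd.DataFrame(rows))
    return design, pd.DataFrame(sample_rows)


def simulate_plexes(cfg: SimConfig) -> tuple[PSMTable, ExperimentalDesign, GroundTruth]:
    """Generate one deterministic multi-plex PSM table under the forward model."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.label_set.n
    design, sample_info = _build_design(cfg)

    # protein catalogue
    prot_rows = []
    abundances: dict[str, np.ndarray] = {}
    for sp in cfg.species:
        ab = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=sp.n_proteins)
        abundances[sp.name] = ab
        for k in range(sp.n_proteins):
            prot_rows.append({"protein_id": f"{sp.name}_{k:04d}", "species": sp.name, "abundance": ab[k]})
    proteins = pd.DataFrame(prot_rows)

    if cfg.batch_factors is not None:
        batch = np.asarray(cfg.batch_factors, dtype=float)
    elif cfg.batch_factor_range is not None:
        lo, hi = cfg.batch_factor_range
        batch = rng.uniform(lo, hi, size=cfg.n_plexes)
    else:
        batch = np.ones(cfg.n_plexes)

    profiles = {sp.name: _channel_profile(cfg, sp) for sp in cfg.species}
    bg_profile = profiles[cfg.background_species] if cfg.background_species else None

    A = (
        build_mixing_matrix(cfg.label_set, cfg.correction_factors).A
        if cfg.correction_factors is not None
        else np.eye(n)
    )
    empty_idx = np.array(
        [i for i, r in enumerate(cfg.channel_roles) if r == "empty"], dtype=int
    )

    meta_frames: list[pd.DataFrame] = []
    clean_blocks: list[np.ndarray] = []
    preleak_blocks: list[np.ndarray] = []
    obs_blocks: list[np.ndarray] = []
    psm_counter = 0
    for p in range(cfg.n_plexes):
        plex = f"plex{p + 1}"
        b = batch[p]
        for sp in cfg.species:
            counts = rng.poisson(cfg.psms_per_protein, size=sp.n_proteins)
            total = int(counts.sum())
            if total == 0:
                continue
            prot_idx = np.repeat(np.arange(sp.n_proteins), counts)
            clean = (
                abundances[sp.name][prot_idx, None] * profiles[sp.name][None, :] * b
            )
            # co-isolation: add f/(1-f) of the background pattern, scaled to
            # the PSM's own total so that the precursor fraction is 1 - f
            f = np.zeros(total)
            if cfg.contamination_max > 0:
                dirty = rng.random(total) >= cfg.contamination_clean_fraction
                f[dirty] = rng.uniform(0.0, cfg.contamination_max, size=int(dirty.sum()))
            preleak = clean.copy()
            if bg_profile is not None and np.any(f > 0):
                bg = bg_profile * b
                bg_total = bg.sum()
                own_total = clean.sum(axis=1)
                scale = np.where(f > 0, f / (1.0 - f) * own_total / bg_total, 0.0)
                preleak = clean + scale[:, None] * bg[None, :]
            obs = preleak @ A
            if cfg.noise_sigma > 0:
                obs = obs * rng.lognormal(0.0, cfg.noise_sigma, size=obs.shape)
            if cfg.empty_noise_floor > 0 and empty_idx.size:
                obs[:, empty_idx] += rng.uniform(
                    0.0, cfg.empty_noise_floor, size=(total, empty_idx.size)
                )
            precursor = rng.lognormal(cfg.precursor_mu, cfg.precursor_sigma, size=total)
            fill = rng.uniform(*cfg.fill_time_range, size=total)
            ids = [f"psm{psm_counter + i:07d}" for i in range(total)]
            psm_counter += total
            meta_frames.append(
                pd.DataFrame(
                    {
                        "psm_id": ids,
                        "protein_group": [f"{sp.name}_{k:04d}" for k in prot_idx],
                        "plex": plex,
                        "experiment": plex,
                        "precursor_intensity": precursor,
                        "fill_time": fill,
                        "pif": 1.0 - f,
                        "base_peak_ratio": np.nan,
                        "species": sp.name,
                    }
                )
            )
            clean_blocks.append(clean)
            preleak_blocks.append(preleak)
            obs_blocks.append(obs)

    if not meta_frames:
        raise ValueError("simulation produced no PSMs; increase psms_per_protein")
    meta_all = pd.concat(meta_frames, ignore_index=True)
    true_clean = np.vstack(clean_blocks)
    true_preleak = np.vstack(preleak_blocks)
    observed = np.vstack(obs_blocks)

    table = PSMTable(
        label_set=cfg.label_set,
        meta=meta_all[META_COLUMNS].copy(),
        raw=observed,
    )
    gt = GroundTruth(
        proteins=proteins,
        sample_info=sample_info,
        condition_amounts=pd.DataFrame(
            {c: {sp.name: sp.condition_amounts[c] for sp in cfg.species} for c in cfg.conditions}
        ),
        reference_amounts={sp.name: sp.reference_amount for sp in cfg.species},
        batch_factors={f"plex{p + 1}": float(batch[p]) for p in range(cfg.n_plexes)},
        psm=meta_all[["psm_id", "protein_group", "species", "plex"]].assign(
            true_pif=meta_all["pif"].to_numpy()
        ),
        true_clean=true_clean,
        true_preleak=true_preleak,
    )
    return table, design, gt


def expected_observed(gt: GroundTruth, cfg: SimConfig) -> np.ndarray:
    """Noise-free expectation of each PSM's observed reporter vector."""
    if cfg.correction_factors is not None:
        A = build_mixing_matrix(cfg.label_set, cfg.correction_factors).A
    else:
        A = np.eye(cfg.label_set.n)
    return gt.true_preleak @ A


# ---------------------------------------------------------------------------
# preset configurations (shipped as TOML files under plexquant/presets)

def _preset_path(name: str) -> Path:
    res = resources.files("plexquant").joinpath("presets", f"{name}.toml")
    with resources.as_file(res) as p:
        return Path(p)


def load_sim_config(path_or_name: str | Path, seed: int = 0, **overrides) -> SimConfig:
    """Load a simulation config from a TOML file or a shipped preset name."""
    if isinstance(path_or_name, str) and path_or_name in PRESET_NAMES:
        path = _preset_path(path_or_name)
    else:
        path = Path(path_or_name)
    with path.open("rb") as fh:
        doc = tomllib.load(fh)
    label_set = load_label_set(doc["label_set"])
    species = tuple(
        SpeciesSpec(
            name=s["name"],
            n_proteins=int(s["n_proteins"]),
            condition_amounts={k: float(v) for k, v in s["condition_amounts"].items()},
            reference_amount=float(s.get("reference_amount", 0.0)),
            carrier_amount=float(s.get("carrier_amount", 0.0)),
        )
        for s in doc["species"]
    )
    cf = None
    if "correction" in doc:
        entries = tuple(
            (src, dst, float(pct) / 100.0) for src, dst, pct in doc["correction"]["entries"]
        )
        cf = CorrectionFactors(label_set=label_set, entries=entries)
    kwargs = dict(
        label_set=label_set,
        channel_roles=tuple(doc["channel_roles"]),
        channel_conditions=tuple(c or None for c in doc["channel_conditions"]),
        species=species,
        n_plexes=int(doc.get("n_plexes", 1)),
        psms_per_protein=float(doc.get("psms_per_protein", 5.0)),
        batch_factor_range=tuple(doc["batch_factor_range"]) if "batch_factor_range" in doc else None,
        noise_sigma=float(doc.get("noise_sigma", 0.1)),
        contamination_clean_fraction=float(doc.get("contamination_clean_fraction", 1.0)),
        contamination_max=float(doc.get("contamination_max", 0.0)),
        background_species=doc.get("background_species") or None,
        correction_factors=cf,
        abundance_sigma=float(doc.get("abundance_sigma", 2.0)),
        empty_noise_floor=float(doc.get("empty_noise_floor", 0.0)),
        seed=seed,
        name=doc.get("name", path.stem),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def get_preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Shipped preset by name: ``ds1_carrier``, ``ds3_two_proteome`` or
    ``ds5_phospho_ratios``; keyword overrides replace any config field."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; known: {', '.join(PRESET_NAMES)}")
    return load_sim_config(name, seed=seed, **overrides)
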