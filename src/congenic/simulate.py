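"""Synthetic paired reciprocal-congenic experiments with known ground truth.

The generator emulates the study design end to end at desk scale: two
independent experiments measuring the same allele contrast (8 vs 8 animals in
experiment A, 6 vs 6 in experiment B), five brain regions per animal, a
defined introgressed interval harboring cis-regulated probe sets whose
allele effect delta_g is identical in the two experiments (both congenics
carry the same two alleles of each interval gene — the biological premise of
the concordance design), optional trans-regulated probe sets outside the
interval, detection dropout, and probe-level data with optional single-probe
SNP-mismatch offsets.

Generative model (log2 scale)::

    value(g, animal i, region r) = baseline_g + region_offset_r
                                   + animal_effect_i + allele_effect_g(i)
                                   + noise          noise ~ N(0, sigma_resid)

with allele_effect = delta_g for iP-allele carriers of regulated probe sets
and 0 otherwise.  Detection calls are Bernoulli with present-probability
logistic in the realized log2 value (midpoint 6, slope 1.5), giving realistic
absent fractions for low expressors.  Probe-level values add a per-probe
affinity offset and probe noise; a designated SNP probe additionally loses
``snp_offset`` log2 units in iNP-allele carriers only, mimicking mismatch
hybridization loss.

Everything is driven by one integer seed through a single
``numpy.random.Generator``; identical seeds give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import DEFAULT_INTERVAL, GenomicInterval, ProbeSetAnnotation, write_annotations
from .errors import ValidationError
from .expression import GROUP_INP, GROUP_IP, REGIONS, ExpressionMatrix
from .probe_snp import ProbeLevelMatrix

__all__ = [
    "SimulationConfig",
    "simulate_congenic_pair",
    "simulate_probe_level",
    "write_experiment_pair",
]

#: Chromosomes used for placing trans/null probe sets (rat autosomes).
_OTHER_CHROMOSOMES = tuple(str(c) for c in range(1, 21) if c != 4)
_GENOME_SPAN = 280_000_000  # generous upper bound for random positions


@dataclass
class SimulationConfig:
    """Parameters of the paired-experiment simulation.

    Defaults reproduce the study conditions: 8 vs 8 animals in experiment A,
    6 vs 6 in experiment B, the five brain regions, and the chromosome 4
    introgressed interval.  Scale parameters are log2 units throughout.
    """

    n_animals_a: int = 8            # per group, experiment A
    n_animals_b: int = 6            # per group, experiment B
    regions: Sequence[str] = REGIONS
    n_probe_sets: int = 2000
    cis_interval: GenomicInterval = DEFAULT_INTERVAL
    n_in_interval: Optional[int] = None   # default: ~3% of n_probe_sets
    frac_cis_regulated: float = 0.15      # of in-interval probe sets
    n_trans_regulated: int = 10
    frac_unplaced: float = 0.02
    delta_sd: float = 0.4           # sd of allele effects (normal, mean 0)
    delta_min: float = 0.1          # resample |delta| below this
    delta_fixed: Optional[float] = None   # if set, |delta| fixed (random sign)
    sigma_resid: float = 0.2
    sigma_animal: float = 0.1
    region_offsets: Optional[Sequence[float]] = None  # default small fixed shifts
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    detection_midpoint: float = 6.0
    detection_slope: float = 1.5
    probes_per_set: int = 11
    probe_affinity_sd: float = 0.5
    frac_snp_probes: float = 0.05   # probe sets given one SNP-offset probe
    snp_offset: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_animals_a", "n_animals_b", "n_probe_sets", "probes_per_set"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("frac_cis_regulated", "frac_snp_probes", "frac_unplaced"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma_resid", "sigma_animal", "delta_sd", "baseline_sd",
                     "probe_affinity_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_trans_regulated < 0:
            raise ValidationError("n_trans_regulated must be >= 0")
        if len(self.regions) < 1:
            raise ValidationError("at least one region required")
        if self.n_in_interval is None:
            self.n_in_interval = max(1, round(0.03 * self.n_probe_sets))
        if self.n_in_interval > self.n_probe_sets:
            raise ValidationError("n_in_interval cannot exceed n_probe_sets")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cis_interval"] = str(self.cis_interval)
        d["regions"] = list(self.regions)
        if d["region_offsets"] is not None:
            d["region_offsets"] = list(d["region_offsets"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _draw_deltas(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    if cfg.delta_fixed is not None:
        sign = rng.choice([-1.0, 1.0], size=n)
        return sign * abs(cfg.delta_fixed)
    delta = rng.normal(0.0, cfg.delta_sd, size=n)
    while True:
        small = np.abs(delta) < cfg.delta_min
        if not small.any():
            return delta
        delta[small] = rng.normal(0.0, cfg.delta_sd, size=int(small.sum()))


def _region_offsets(cfg: SimulationConfig) -> np.ndarray:
    if cfg.region_offsets is not None:
        offs = np.asarray(cfg.region_offsets, dtype=float)
        if len(offs) != len(cfg.regions):
            raise ValidationError("region_offsets must match the number of regions")
        return offs
    # fixed, deterministic baseline shifts cycling over the regions
    base = np.array([0.0, 0.2, -0.1, 0.1, -0.2])
    return np.resize(base, len(cfg.regions))


def _simulate_experiment(
    rng: np.random.Generator,
    label: str,
    n_per_group: int,
    baseline: np.ndarray,
    delta: np.ndarray,
    cfg: SimulationConfig,
    probe_ids: list[str],
) -> ExpressionMatrix:
    regions = list(cfg.regions)
    offsets = _region_offsets(cfg)
    groups = [GROUP_IP] * n_per_group + [GROUP_INP] * n_per_group
    animals = [f"{label}_{'iPc' if g == GROUP_IP else 'iNPc'}{i % n_per_group + 1:02d}"
               for i, g in enumerate(groups)]
    n_animals = len(animals)
    animal_eff = rng.normal(0.0, cfg.sigma_animal, size=n_animals)
    carrier = np.array([g == GROUP_IP for g in groups], dtype=float)

    G = len(probe_ids)
    # values[g, animal, region]
    vals = (
        baseline[:, None, None]
        + offsets[None, None, :]
        + animal_eff[None, :, None]
        + (delta[:, None] * carrier[None, :])[:, :, None]
        + rng.normal(0.0, cfg.sigma_resid, size=(G, n_animals, len(regions)))
    )
    sample_ids = [f"{a}_{r}" for a in animals for r in regions]
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "animal_id": np.repeat(animals, len(regions)),
            "group": np.repeat(groups, len(regions)),
            "region": np.tile(regions, n_animals),
        }
    )
    flat = vals.reshape(G, n_animals * len(regions))
    values = pd.DataFrame(flat, index=pd.Index(probe_ids, name="probe_set_id"),
                          columns=sample_ids)
    p_present = 1.0 / (1.0 + np.exp(-cfg.detection_slope * (flat - cfg.detection_midpoint)))
    detection = pd.DataFrame(
        rng.random(flat.shape) < p_present, index=values.index, columns=sample_ids
    )
    return ExpressionMatrix(values, sheet, detection)


def simulate_congenic_pair(cfg: SimulationConfig):
    """Simulate the paired experiments.

    Returns ``(matrix_a, matrix_b, annotations, truth)`` where *truth* is a
    DataFrame with columns ``probe_set_id, locus_class`` (cis / trans / null),
    ``true_delta`` (0 iff null) and ``snp_probe_id`` (the designated
    SNP-artifact probe, or missing).  Allele effects are identical in the two
    experiments; all other randomness is experiment-specific.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_probe_sets
    probe_ids = [f"ps{i + 1:05d}_at" for i in range(G)]

    # --- genomic placement -------------------------------------------------
    n_in = cfg.n_in_interval
    n_unplaced = int(round(cfg.frac_unplaced * (G - n_in)))
    idx = np.arange(G)
    in_interval = idx < n_in
    unplaced = (idx >= n_in) & (idx < n_in + n_unplaced)
    chrom = np.empty(G, dtype=object)
    pos = np.empty(G, dtype=object)
    sym = [f"Gene{i + 1}" for i in range(G)]
    chrom[in_interval] = cfg.cis_interval.chromosome
    pos[in_interval] = rng.integers(cfg.cis_interval.start, cfg.cis_interval.end + 1,
                                    size=n_in)
    chrom[unplaced] = None
    pos[unplaced] = None
    n_out = G - n_in - n_unplaced
    chrom[~in_interval & ~unplaced] = rng.choice(_OTHER_CHROMOSOMES, size=n_out)
    pos[~in_interval & ~unplaced] = rng.integers(1, _GENOME_SPAN, size=n_out)
    annotations = [
        ProbeSetAnnotation(pid, c, None if p is None else int(p), s)
        for pid, c, p, s in zip(probe_ids, chrom, pos, sym)
    ]

    # --- ground truth ------------------------------------------------------
    n_cis = int(round(cfg.frac_cis_regulated * n_in))
    cis_idx = rng.choice(np.flatnonzero(in_interval), size=n_cis, replace=False)
    placed_out = np.flatnonzero(~in_interval & ~unplaced)
    if cfg.n_trans_regulated > len(placed_out):
        raise ValidationError("n_trans_regulated exceeds the placed out-of-interval probe sets")
    trans_idx = rng.choice(placed_out, size=cfg.n_trans_regulated, replace=False)
    delta = np.zeros(G)
    delta[cis_idx] = _draw_deltas(rng, n_cis, cfg)
    delta[trans_idx] = _draw_deltas(rng, cfg.n_trans_regulated, cfg)
    locus = np.array(["null"] * G, dtype=object)
    locus[cis_idx] = "cis"
    locus[trans_idx] = "trans"

    # --- designated SNP probes (consumed by simulate_probe_level) ----------
    snp_probe = np.array([None] * G, dtype=object)
    n_snp = int(round(cfg.frac_snp_probes * G))
    if n_snp and cfg.probes_per_set >= 1:
        snp_sets = rng.choice(G, size=n_snp, replace=False)
        which = rng.integers(0, cfg.probes_per_set, size=n_snp)
        for g, w in zip(snp_sets, which):
            snp_probe[g] = f"{probe_ids[g]}_p{w + 1:02d}"

    truth = pd.DataFrame(
        {
            "probe_set_id": probe_ids,
            "locus_class": locus,
            "true_delta": delta,
            "snp_probe_id": snp_probe,
        }
    )

    # --- baselines shared across experiments -------------------------------
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=G)
    mat_a = _simulate_experiment(rng, "A", cfg.n_animals_a, baseline, delta, cfg, probe_ids)
    mat_b = _simulate_experiment(rng, "B", cfg.n_animals_b, baseline, delta, cfg, probe_ids)
    return mat_a, mat_b, annotations, truth


def simulate_probe_level(
    cfg: SimulationConfig,
    truth: pd.DataFrame,
    experiment: str = "A",
) -> ProbeLevelMatrix:
    """Simulate probe-within-probe-set intensities for one experiment.

    probe value = probe-set signal + per-probe affinity offset + probe noise,
    minus ``snp_offset`` for the truth-designated SNP probe in iNP-allele
    carriers only.  Consistent with the probe-set matrix in expectation
    (affinity offsets have mean zero).  Deterministic given ``cfg.seed``; a
    seed substream distinct from :func:`simulate_congenic_pair` is used so the
    two outputs are independent draws from the same model.
    """
    if experiment not in ("A", "B"):
        raise ValidationError(f"experiment must be 'A' or 'B', got {experiment!r}")
    rng = np.random.default_rng((cfg.seed, 1, 0 if experiment == "A" else 1))
    probe_ids_sets = truth["probe_set_id"].tolist()
    delta = truth["true_delta"].to_numpy(dtype=float)
    snp_probe = truth["snp_probe_id"].to_numpy(dtype=object)
    G = len(probe_ids_sets)
    P = cfg.probes_per_set
    n_per_group = cfg.n_animals_a if experiment == "A" else cfg.n_animals_b
    regions = list(cfg.regions)
    offsets = _region_offsets(cfg)
    groups = [GROUP_IP] * n_per_group + [GROUP_INP] * n_per_group
    animals = [f"{experiment}_{'iPc' if g == GROUP_IP else 'iNPc'}{i % n_per_group + 1:02d}"
               for i, g in enumerate(groups)]
    n_animals = len(animals)
    carrier = np.array([g == GROUP_IP for g in groups], dtype=float)

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=G)
    animal_eff = rng.normal(0.0, cfg.sigma_animal, size=n_animals)
    affinity = rng.normal(0.0, cfg.probe_affinity_sd, size=(G, P))

    # signal[g, animal, region] at the probe-set level
    signal = (
        baseline[:, None, None]
        + offsets[None, None, :]
        + animal_eff[None, :, None]
        + (delta[:, None] * carrier[None, :])[:, :, None]
    )
    # probe values: expand to (G, P, animals, regions)
    vals = (
        signal[:, None, :, :]
        + affinity[:, :, None, None]
        + rng.normal(0.0, cfg.sigma_resid, size=(G, P, n_animals, len(regions)))
    )
    probe_ids = [f"{ps}_p{j + 1:02d}" for ps in probe_ids_sets for j in range(P)]
    # SNP mismatch loss in iNP-allele carriers only
    noncarrier = carrier == 0
    for g in range(G):
        if snp_probe[g] is not None and not pd.isna(snp_probe[g]):
            j = int(str(snp_probe[g]).rsplit("_p", 1)[1]) - 1
            vals[g, j, noncarrier, :] -= cfg.snp_offset

    sample_ids = [f"{a}_{r}" for a in animals for r in regions]
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "animal_id": np.repeat(animals, len(regions)),
            "group": np.repeat(groups, len(regions)),
            "region": np.tile(regions, n_animals),
        }
    )
    flat = vals.reshape(G * P, n_animals * len(regions))
    values = pd.DataFrame(flat, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    probe_sets = pd.Series(np.repeat(probe_ids_sets, P), index=values.index, name="probe_set_id")
    return ProbeLevelMatrix(values, probe_sets, sheet)


def write_experiment_pair(cfg: SimulationConfig, out_dir, probe_level: bool = False) -> dict:
    """Simulate and write the full TSV bundle consumed by the pipeline.

    Writes, per experiment X in {a, b}: ``expression_X.tsv``,
    ``detection_X.tsv``, ``samples_X.tsv``; plus ``annotations.tsv``,
    ``truth.tsv``, optionally ``probe_level_a.tsv``, and a ``manifest.json``
    recording the seed and a hash of the configuration.  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat_a, mat_b, annotations, truth = simulate_congenic_pair(cfg)
    files = {}
    for label, mat in (("a", mat_a), ("b", mat_b)):
        paths = {
            f"expression_{label}": out / f"expression_{label}.tsv",
            f"samples_{label}": out / f"samples_{label}.tsv",
            f"detection_{label}": out / f"detection_{label}.tsv",
        }
        mat.to_tsv(paths[f"expression_{label}"], paths[f"samples_{label}"],
                   paths[f"detection_{label}"])
        files.update({k: str(v) for k, v in paths.items()})
    write_annotations(annotations, out / "annotations.tsv")
    files["annotations"] = str(out / "annotations.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6g")
    files["truth"] = str(out / "truth.tsv")
    if probe_level:
        plm = simulate_probe_level(cfg, truth, "A")
        plm.to_tsv(out / "probe_level_a.tsv")
        files["probe_level_a"] = str(out / "probe_level_a.tsv")
    manifest = {"seed": cfg.seed, "config_hash": cfg.config_hash(), "config": cfg.to_dict(),
                "files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
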