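"""Seeded generators for multi-epitope AP-MS studies and BN-gel slice profiles.

The AP-MS generator emulates the design of a multi-epitope affinity
purification study of a low-abundance membrane channel: several bait
antibodies crossed with two solubilisation detergents, target-unrelated
control (TUC) antibody pull-downs and knock-out (KO) pull-downs as stringent
negative controls, background binders spanning several orders of magnitude
in abundance, smooth monotone retention-time drift between runs, a constant
ppm-scale m/z offset per run, log-normal peak-volume noise, a peak-volume
detection floor, and random feature dropout. Every planted quantity is
recorded in a :class:`GroundTruth` so downstream stages can be scored.

The BN-gel generator plants Gaussian abundance peaks on a 192-slice native
gel whose slice -> log10(mass) relation is a known 4-parameter logistic,
with marker complexes of known mass for calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    DETERGENTS,
    ProteinRecord,
    RunMeta,
    RunTable,
    StudyBundle,
    write_fasta,
    write_feature_table,
)
from .masses import DigestParams, peptide_mz, tryptic_digest

__all__ = [
    "ApSimConfig",
    "BnSimConfig",
    "GroundTruth",
    "SliceProfileBundle",
    "simulate_apms_study",
    "simulate_complexome",
    "paper_like_apms_config",
    "null_apms_config",
    "paper_like_complexome_config",
    "write_fixture_set",
    "PRESETS",
]

_RESIDUES_NO_KR = np.array(list("ACDEFGHILMNQSTVWY"))  # P excluded after K/R handling


@dataclass(frozen=True)
class ApSimConfig:
    """Study-design and noise parameters of the AP-MS simulator.

    Defaults mirror the emulated study: 5 bait antibodies and 5 TUC
    antibodies under two detergents with KO controls, 5 planted partners
    among >= 500 background proteins, background abundances log-uniform over
    4 decades, log-normal peak-volume noise, ppm-scale constant m/z offsets
    and minute-scale monotone RT drift.
    """

    n_background_proteins: int = 500
    n_true_partners: int = 5
    n_antibodies_target: int = 5
    n_tuc_controls: int = 5
    include_ko_controls: bool = True
    detergents: tuple[str, ...] = ("CL-47", "CL-91")
    bait_abundance: float = 1e8
    partner_ratio_to_bait: tuple[float, ...] = (1.0, 0.1, 0.1, 0.1, 0.01)
    enrichment_fold: float = math.inf
    pv_lognormal_sigma: float = 0.5
    dynamic_range_decades: float = 4.0
    rt_drift_amplitude: float = 2.0
    mz_offset_ppm_range: float = 10.0
    mz_noise_ppm: float = 0.5
    dropout_prob: float = 0.15
    peptides_per_protein: tuple[int, int] = (4, 10)
    pv_detection_limit: float = 1e3
    partner_cl91_attenuation: float = 0.1
    rt_jitter_sd: float = 0.05
    gradient_minutes: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_background_proteins,
            self.n_true_partners,
            self.n_antibodies_target,
            self.n_tuc_controls,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if not self.detergents:
            raise ValueError("detergents must be non-empty")
        for d in self.detergents:
            if d not in DETERGENTS:
                raise ValueError(f"unknown detergent {d!r}")
        if len(self.partner_ratio_to_bait) < self.n_true_partners:
            raise ValueError("need one partner_ratio_to_bait per planted partner")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must be > 1 (inf = absent from controls)")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("peptides_per_protein must be a range (lo >= 1, hi >= lo)")


@dataclass
class GroundTruth:
    """Planted truth of a simulated AP-MS study."""

    bait_id: str
    partner_ids: set[str]
    partner_true_ratio: dict[str, float]
    run_warps: dict[str, dict[str, list[float]]]
    run_mz_offset_ppm: dict[str, float]
    true_abundance: dict[tuple[str, str], float]
    peptide_true_rt: dict[tuple[str, int], float] = field(default_factory=dict)


def _random_tryptic_block(rng: np.random.Generator, lo: int = 6, hi: int = 16) -> str:
    """A tryptic peptide: non-K/R body ending in K or R (never before P here)."""
    n = int(rng.integers(lo, hi + 1))
    body = "".join(rng.choice(_RESIDUES_NO_KR, size=n))
    return body + ("K" if rng.random() < 0.5 else "R")


def _make_protein(
    rng: np.random.Generator, n_peptides: int, seen: set[str]
) -> tuple[str, list[str]]:
    """A protein sequence built from globally unique tryptic blocks."""
    peps: list[str] = []
    while len(peps) < n_peptides:
        pep = _random_tryptic_block(rng)
        if pep not in seen:
            seen.add(pep)
            peps.append(pep)
    return "".join(peps), peps


def _monotone_warp(rng: np.random.Generator, amplitude: float, t_max: float):
    """A strictly increasing smooth RT distortion over [0, t_max].

    Returns (knots, values); evaluate with PCHIP interpolation. Values are
    knots plus a bounded smooth perturbation, repaired to be increasing.
    """
    from scipy.interpolate import PchipInterpolator

    knots = np.linspace(0.0, t_max, 6)
    perturb = rng.uniform(-amplitude, amplitude, size=knots.size)
    perturb[0] = perturb[-1] = rng.uniform(-amplitude / 4, amplitude / 4)
    values = knots + perturb
    # enforce strict monotonicity with a minimal slope between knots
    min_step = 0.2 * (knots[1] - knots[0])
    for i in range(1, values.size):
        values[i] = max(values[i], values[i - 1] + min_step)
    interp = PchipInterpolator(knots, values, extrapolate=True)
    return knots, values, interp


def simulate_apms_study(config: ApSimConfig) -> tuple[StudyBundle, GroundTruth]:
    """Simulate a full multi-antibody AP-MS study with planted ground truth.

    One run per (target antibody x detergent), per (TUC antibody x
    detergent), and - when KO controls are enabled - per (target antibody x
    detergent) on the knock-out background. Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    t_max = config.gradient_minutes

    # ---- protein universe -------------------------------------------------
    seen_peptides: set[str] = set()
    proteins: list[ProteinRecord] = []
    observable: dict[str, list[str]] = {}

    def add_protein(pid: str, n_pep: int, desc: str) -> None:
        seq, peps = _make_protein(rng, n_pep, seen_peptides)
        proteins.append(ProteinRecord(pid, seq, desc))
        observable[pid] = peps

    lo, hi = config.peptides_per_protein
    bait_id = "BAIT001"
    add_protein(bait_id, hi, "simulated bait channel subunit")
    partner_ids = [f"PARTNER{i + 1:02d}" for i in range(config.n_true_partners)]
    for pid in partner_ids:
        add_protein(pid, int(rng.integers(lo, hi + 1)), "simulated true partner")
    background_ids = [f"BG{i + 1:04d}" for i in range(config.n_background_proteins)]
    for pid in background_ids:
        add_protein(pid, int(rng.integers(lo, hi + 1)), "simulated background binder")

    # fixed per-peptide properties: charge, theoretical m/z, true RT, response
    pep_charge: dict[str, int] = {}
    pep_mz: dict[str, float] = {}
    pep_rt: dict[str, float] = {}
    pep_resp: dict[str, float] = {}
    for pid, peps in observable.items():
        for pep in peps:
            z = int(rng.choice([2, 3], p=[0.7, 0.3]))
            pep_charge[pep] = z
            pep_mz[pep] = peptide_mz(pep, z)
            pep_rt[pep] = float(rng.uniform(0.04, 0.96) * t_max)
            pep_resp[pep] = float(np.exp(rng.normal(0.0, 0.5)))

    # study-level background abundances: log-uniform over the dynamic range
    bg_abundance = {
        pid: float(
            10
            ** rng.uniform(
                math.log10(config.bait_abundance) - config.dynamic_range_decades,
                math.log10(config.bait_abundance),
            )
        )
        for pid in background_ids
    }
    partner_ratio = {
        pid: float(config.partner_ratio_to_bait[i]) for i, pid in enumerate(partner_ids)
    }

    # ---- run roster -------------------------------------------------------
    roster: list[RunMeta] = []
    for det in config.detergents:
        for a in range(config.n_antibodies_target):
            ab = f"abM7-{chr(ord('a') + a)}"
            roster.append(RunMeta(f"AP_{ab}_{det}", ab, "target_ap", det))
        for a in range(config.n_tuc_controls):
            ab = f"abTUC-{a + 1}"
            roster.append(RunMeta(f"TUC_{ab}_{det}", ab, "tuc_control", det))
        if config.include_ko_controls:
            for a in range(config.n_antibodies_target):
                ab = f"abM7-{chr(ord('a') + a)}"
                roster.append(RunMeta(f"KO_{ab}_{det}", ab, "ko_control", det))

    truth = GroundTruth(
        bait_id=bait_id,
        partner_ids=set(partner_ids),
        partner_true_ratio=partner_ratio,
        run_warps={},
        run_mz_offset_ppm={},
        true_abundance={},
        peptide_true_rt={pep: pep_rt[pep] for pep in pep_rt},
    )

    runs: list[RunTable] = []
    for meta in roster:
        knots, values, warp = _monotone_warp(rng, config.rt_drift_amplitude, t_max)
        offset_ppm = float(rng.uniform(-config.mz_offset_ppm_range, config.mz_offset_ppm_range))
        truth.run_warps[meta.run_id] = {"knots": list(knots), "values": list(values)}
        truth.run_mz_offset_ppm[meta.run_id] = offset_ppm

        # protein levels present in this run
        levels: dict[str, float] = dict(bg_abundance)
        if meta.sample_class == "target_ap":
            levels[bait_id] = config.bait_abundance
            for pid in partner_ids:
                lvl = config.bait_abundance * partner_ratio[pid]
                if meta.detergent == "CL-91":
                    lvl *= config.partner_cl91_attenuation
                levels[pid] = lvl
        elif math.isfinite(config.enrichment_fold):
            for pid in partner_ids:
                levels[pid] = config.bait_abundance * partner_ratio[pid] / config.enrichment_fold

        rows: list[tuple] = []
        for pid, level in levels.items():
            expected_total = 0.0
            for pep in observable[pid]:
                mu = level * pep_resp[pep]
                expected_total += mu
                pv = mu * float(np.exp(rng.normal(0.0, config.pv_lognormal_sigma)))
                dropped = rng.random() < config.dropout_prob or pv < config.pv_detection_limit
                if dropped:
                    continue
                rt_obs = float(warp(pep_rt[pep]) + rng.normal(0.0, config.rt_jitter_sd))
                ppm = offset_ppm + rng.normal(0.0, config.mz_noise_ppm)
                mz_obs = pep_mz[pep] * (1.0 + ppm * 1e-6)
                rows.append(
                    (pid, pep, pep_charge[pep], pep_mz[pep], mz_obs, max(rt_obs, 0.0), pv)
                )
            truth.true_abundance[(pid, meta.run_id)] = expected_total
        features = pd.DataFrame(
            rows,
            columns=[
                "protein_id",
                "peptide_seq",
                "charge",
                "mz_theoretical",
                "mz_observed",
                "rt",
                "pv",
            ],
        )
        runs.append(RunTable(meta=meta, features=features))

    bundle = StudyBundle(runs=runs, proteins=proteins, ground_truth=truth)
    return bundle, truth


# --------------------------------------------------------------------------
# BN-gel complexome simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BnSimConfig:
    """Parameters of the BN-gel slice-profile simulator.

    ``calibration_curve`` holds the true 4-parameter logistic
    (a, d, s0, b) of log10(mass kDa) versus slice number: slice 1 is the gel
    top (largest mass) and log-mass decreases monotonically with slice.
    ``noise_sigma`` is multiplicative (log-normal) noise on slice peak
    volumes; ``marker_logmass_jitter`` jitters every complex's migration by
    a log10-mass sigma, emulating gel irregularity (2% by default).
    """

    n_slices: int = 192
    complexes: tuple[tuple[str, float, float, float], ...] = (
        ("BAIT_COMPLEX", 1400.0, 1.0e6, 4.0),
    )
    markers: tuple[tuple[str, float], ...] = (
        ("MARKER_3000", 3000.0),
        ("MARKER_1500", 1500.0),
        ("MARKER_1000", 1000.0),
        ("MARKER_0720", 720.0),
        ("MARKER_0480", 480.0),
        ("MARKER_0230", 230.0),
        ("MARKER_0140", 140.0),
    )
    calibration_curve: tuple[float, float, float, float] = (3.8, 1.4, 80.0, 40.0)
    noise_sigma: float = 0.05
    marker_logmass_jitter: float = 0.02
    marker_amplitude: float = 1.0e7
    marker_width_slices: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 10:
            raise ValueError("n_slices must be >= 10")
        if len(self.markers) < 4:
            raise ValueError("need >= 4 markers for calibration")
        for name, mass, *_ in [*self.complexes, *self.markers]:
            if mass <= 0:
                raise ValueError(f"complex {name!r}: mass must be > 0")


@dataclass
class SliceProfileBundle:
    """Protein x slice peak-volume matrix plus the marker table."""

    matrix: pd.DataFrame  # rows: protein_id; columns: slice_0001..slice_N
    markers: pd.DataFrame  # columns: protein_id, mass_kda

    @property
    def n_slices(self) -> int:
        return self.matrix.shape[1]


def _true_logmass(s: np.ndarray | float, curve: tuple[float, float, float, float]) -> np.ndarray:
    a, d, s0, b = curve
    return d + (a - d) / (1.0 + np.exp((np.asarray(s, dtype=float) - s0) / b))


def _invert_logmass(y: float, curve: tuple[float, float, float, float]) -> float:
    a, d, s0, b = curve
    if not (min(a, d) < y < max(a, d)):
        raise ValueError(f"log10 mass {y:.3f} outside calibration range ({d:.2f}, {a:.2f})")
    return s0 + b * math.log((a - d) / (y - d) - 1.0)


def simulate_complexome(config: BnSimConfig) -> tuple[SliceProfileBundle, dict]:
    """Simulate a BN-gel slice series with Gaussian complex peaks.

    Each complex (markers included) migrates to the slice implied by its
    true mass through the calibration logistic, jittered by
    ``marker_logmass_jitter`` in log10(mass); profiles carry multiplicative
    log-normal noise. Returns the bundle plus a truth record with the true
    curve and planted peak centers. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    slices = np.arange(1, config.n_slices + 1, dtype=float)

    entries = [
        (name, mass, amp, width)
        for (name, mass, amp, width) in config.complexes
    ] + [
        (name, mass, config.marker_amplitude, config.marker_width_slices)
        for (name, mass) in config.markers
    ]

    rows = {}
    truth: dict = {
        "calibration_curve": tuple(config.calibration_curve),
        "true_center_slice": {},
        "true_mass_kda": {},
        "marker_ids": [name for name, _ in config.markers],
    }
    for name, mass, amp, width in entries:
        y = math.log10(mass)
        center_exact = _invert_logmass(y, config.calibration_curve)  # validates range
        y_jit = y + rng.normal(0.0, config.marker_logmass_jitter)
        try:
            center = _invert_logmass(y_jit, config.calibration_curve)
        except ValueError:
            center = center_exact
        profile = amp * np.exp(-0.5 * ((slices - center) / width) ** 2)
        profile = profile * np.exp(rng.normal(0.0, config.noise_sigma, size=slices.size))
        profile[profile < amp * 1e-6] = 0.0
        rows[name] = profile
        truth["true_center_slice"][name] = center
        truth["true_mass_kda"][name] = mass

    matrix = pd.DataFrame(
        rows, index=[f"slice_{i:04d}" for i in range(1, config.n_slices + 1)]
    ).T
    markers = pd.DataFrame(
        [(name, mass) for name, mass in config.markers],
        columns=["protein_id", "mass_kda"],
    )
    return SliceProfileBundle(matrix=matrix, markers=markers), truth


# --------------------------------------------------------------------------
# Fixture presets
# --------------------------------------------------------------------------

def paper_like_apms_config(seed: int = 0, **overrides) -> ApSimConfig:
    """The default study design: 5 planted partners among 500 background
    proteins, 5 target antibodies, 5 TUC antibodies, KO controls, two
    detergents, partners absent from every negative control."""
    return ApSimConfig(seed=seed, **overrides)


def null_apms_config(seed: int = 0, **overrides) -> ApSimConfig:
    """Same design with zero planted partners (negative-control study)."""
    overrides.setdefault("n_true_partners", 0)
    return ApSimConfig(seed=seed, **overrides)


def paper_like_complexome_config(seed: int = 0, **overrides) -> BnSimConfig:
    """192 slices, 7 markers spanning 140-3000 kDa, bait complex at 1400 kDa."""
    return BnSimConfig(seed=seed, **overrides)


PRESETS = {
    "paper_like_apms": paper_like_apms_config,
    "null_apms": null_apms_config,
    "paper_like_complexome": paper_like_complexome_config,
}


def write_fixture_set(out_dir: str | Path, preset: str, seed: int = 0) -> dict:
    """Write a named fixture preset (TSV/FASTA/YAML) and return its manifest."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"preset": preset, "seed": seed, "files": []}

    if preset in ("paper_like_apms", "null_apms"):
        config = PRESETS[preset](seed=seed)
        bundle, truth = simulate_apms_study(config)
        for run in bundle.runs:
            fname = f"{run.meta.run_id}.tsv"
            write_feature_table(run, out / fname)
            manifest["files"].append(fname)
        write_fasta(bundle.proteins, out / "proteins.fasta")
        manifest["files"].append("proteins.fasta")
        truth_doc = {
            "bait_id": truth.bait_id,
            "partner_ids": sorted(truth.partner_ids),
            "partner_true_ratio": dict(sorted(truth.partner_true_ratio.items())),
            "run_mz_offset_ppm": {
                k: float(v) for k, v in sorted(truth.run_mz_offset_ppm.items())
            },
            "run_warps": {
                k: {kk: [float(x) for x in vv] for kk, vv in truth.run_warps[k].items()}
                for k in sorted(truth.run_warps)
            },
        }
        (out / "truth.yaml").write_text(yaml.safe_dump(truth_doc, sort_keys=False))
        manifest["files"].append("truth.yaml")
        manifest["config"] = asdict(config)
        manifest["config"]["detergents"] = list(config.detergents)
    else:
        config = paper_like_complexome_config(seed=seed)
        bundle, truth = simulate_complexome(config)
        bundle.matrix.to_csv(out / "slice_matrix.tsv", sep="\t", index_label="protein_id")
        bundle.markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        manifest["files"] += ["slice_matrix.tsv", "markers.tsv"]
        truth_doc = {
            "calibration_curve": list(truth["calibration_curve"]),
            "true_mass_kda": truth["true_mass_kda"],
            "true_center_slice": {k: float(v) for k, v in truth["true_center_slice"].items()},
        }
        (out / "truth.yaml").write_text(yaml.safe_dump(truth_doc, sort_keys=False))
        manifest["files"].append("truth.yaml")
        cfg = asdict(config)
        cfg["complexes"] = [list(c) for c in config.complexes]
        cfg["markers"] = [list(m) for m in config.markers]
        cfg["calibration_curve"] = list(config.calibration_curve)
        manifest["config"] = cfg

    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest
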