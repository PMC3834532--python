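"""End-to-end workflow over a synthetic two-state system.

Stage order mirrors the analysis of a receptor trajectory: synthesize (or
load) a trajectory -> align & per-frame metrics -> essential-dynamics PCA
-> membrane-embedded ANM -> PCA/ANM subspace overlap -> RMSD clustering.
All randomness flows from the single config seed; the config (with its
hash) is serialized next to the outputs so a run can be reproduced
bit-for-bit for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .anm import build_hessian, restrict_modes, solve_modes
from .cluster import occupancy, rmsd_cluster
from .essential import align_trajectory, pca
from .membrane import DEFAULT_CUTOFF, DEFAULT_GAMMAS, build_fcc_slab, embed
from .metrics import com_offset_profile, rmsd_profile, rmsf
from .overlap import average_overlap, overlap_matrix, region_overlap
from .structures import select, write_structure, write_trajectory
from .synthetic import SyntheticSpec, default_state_shift, make_bundle, make_trajectory

__all__ = ["RunConfig", "build_system", "synthesize_trajectory", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run (defaults reproduce the demo
    conditions: a 330-residue bundle, 1000 frames, packing transition at
    70% of the run, membrane ANM with gammas 1/2/4 at 11 A cutoff)."""

    seed: int = 0
    n_frames: int = 1000
    noise_sd: float = 0.3
    transition_fraction: float = 0.7
    shift_norm: float = 25.0
    rigid_jitter: tuple[float, float] = (5.0, 2.0)
    n_planted_modes: int = 10
    planted_variance_scale: float = 8.0  # A^2 variance of the slowest planted mode
    # membrane / ANM
    slab_diameter: float = 80.0
    slab_thickness: float = 33.0
    nn_spacing: float = 8.0
    clash_radius: float = 4.0
    cutoff: float = DEFAULT_CUTOFF
    gammas: tuple[float, float, float] = (1.0, 2.0, 4.0)  # pp, pm, mm
    n_anm_modes: int = 20
    # PCA / overlap / clustering
    pca_fit_region: str = "ALL"
    n_pca_modes: int = 20
    overlap_k: int = 10
    cluster_fit_region: str = "TMEMB"
    cluster_measure_region: str = "INTRA"
    cluster_cutoff: float = 1.8
    out_dir: str = "results/pipeline"

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # scientific parameters only
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:10]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("rigid_jitter", "mode_variances", "gammas"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write_profile(profile, path: Path, config_hash: str) -> None:
    header = (f"# config_hash={config_hash} kind={profile.kind} "
              f"units={profile.units} descriptor={profile.descriptor}\n"
              f"time_ns\tvalue\n")
    body = "\n".join(f"{t:.4f}\t{v:.6f}" for t, v in zip(profile.times, profile.values))
    path.write_text(header + body + "\n")


def build_system(config: RunConfig):
    """Stage 1: bundle, membrane network and its intrinsic (ANM) modes.

    Returns (bundle, network, anm_modes, protein_modes)."""
    spec = SyntheticSpec(seed=config.seed, n_frames=config.n_frames,
                         noise_sd=config.noise_sd,
                         rigid_jitter=config.rigid_jitter)
    bundle = make_bundle(spec)
    slab = build_fcc_slab(config.slab_diameter, config.slab_thickness,
                          config.nn_spacing)
    g_pp, g_pm, g_mm = config.gammas
    gamma_map = {("protein", "protein"): g_pp, ("protein", "membrane"): g_pm,
                 ("membrane", "membrane"): g_mm}
    network = embed(bundle, slab, config.clash_radius, "TMEMB",
                    config.cutoff, gamma_map)
    hessian = build_hessian(network)
    anm_modes = solve_modes(hessian, n_modes=config.n_anm_modes)
    protein_modes = restrict_modes(anm_modes, network.protein_indices())
    return bundle, network, anm_modes, protein_modes


def synthesize_trajectory(config: RunConfig, bundle, anm_modes, protein_modes):
    """Stage 2: two-state trajectory whose fluctuations follow the slowest
    protein-restricted intrinsic modes (orthonormalized, thermal-like
    1/lambda variances); the packing transition is a mean shift on the
    loop + lower helix, orthogonalized against the planted modes so the
    step is a distinct degree of freedom.

    Returns (spec, trajectory, ground_truth)."""
    spec = SyntheticSpec(seed=config.seed, n_frames=config.n_frames,
                         noise_sd=config.noise_sd,
                         rigid_jitter=config.rigid_jitter)
    n_plant = config.n_planted_modes
    q, _ = np.linalg.qr(protein_modes.vectors[:, :n_plant])
    planted = q.T
    lam = anm_modes.eigenvalues[:n_plant]
    variances = config.planted_variance_scale * lam[0] / lam
    variances = np.sort(variances)[::-1]
    shift = default_state_shift(bundle, norm=config.shift_norm)
    shift = shift - planted.T @ (planted @ shift)
    shift *= config.shift_norm / np.linalg.norm(shift)
    spec.planted_modes = planted
    spec.mode_variances = variances
    spec.transition_frame = int(config.transition_fraction * config.n_frames)
    spec.state_shift = shift
    traj, truth = make_trajectory(bundle, spec)
    return spec, traj, truth


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write profiles, mode files, overlap matrices and
    cluster tables plus a ``summary.json`` to the output directory. Returns
    the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(out / "config.yaml")
    logger.info("pipeline run: seed=%d config_hash=%s", config.seed, chash)

    bundle, network, anm_modes, protein_modes = build_system(config)
    write_structure(bundle, out / f"{chash}_bundle.pdb")
    np.savetxt(out / f"{chash}_anm_eigenvalues.tsv", anm_modes.eigenvalues,
               header=f"config_hash={chash}\nanm_eigenvalue")
    spec, traj, truth = synthesize_trajectory(config, bundle, anm_modes,
                                              protein_modes)
    truth.to_json(out / f"{chash}_ground_truth.json")

    # --- align & metrics ----------------------------------------------
    aligned = align_trajectory(traj, 0, "CORE")
    for fit in ("ALL", "CORE", "TMEMB"):
        prof = rmsd_profile(traj, 0, fit_region=fit, measure_region=fit)
        _write_profile(prof, out / f"{chash}_rmsd_{fit}.tsv", chash)
    loop_prof = rmsd_profile(traj, 0, fit_region="CORE", measure_region="ICL3")
    _write_profile(loop_prof, out / f"{chash}_rmsd_ICL3_fit_CORE.tsv", chash)
    x_off = com_offset_profile(aligned, "CORE", "ICL3", "x")
    y_off = com_offset_profile(aligned, "CORE", "ICL3", "y")
    _write_profile(x_off, out / f"{chash}_offset_x.tsv", chash)
    _write_profile(y_off, out / f"{chash}_offset_y.tsv", chash)
    full_rmsf = rmsf(traj, "CORE")
    t_hi = float(traj.times[-1])
    late_rmsf = rmsf(traj, "CORE", (config.transition_fraction * t_hi, t_hi))
    np.savetxt(out / f"{chash}_rmsf.tsv",
               np.column_stack([full_rmsf.residue_indices, full_rmsf.values,
                                late_rmsf.values]),
               header=f"config_hash={chash}\nresidue\trmsf_full_A\trmsf_late_A",
               delimiter="\t", fmt=["%d", "%.6f", "%.6f"])

    # --- essential dynamics -------------------------------------------
    aligned_pca = (aligned if config.pca_fit_region == "CORE"
                   else align_trajectory(traj, 0, config.pca_fit_region))
    result = pca(aligned_pca, n_modes=config.n_pca_modes)
    fractions = result.variance_fractions

    # --- overlap --------------------------------------------------------
    k = config.overlap_k
    o_matrix = overlap_matrix(result.eigenvectors[:, :k],
                              protein_modes.vectors[:, :k])
    o_ave = average_overlap(result, protein_modes, k=k)
    np.savetxt(out / f"{chash}_overlap_matrix.tsv", o_matrix.values,
               header=f"config_hash={chash}\nO_ij = |p_i . u_j|, k={k}")
    loop_nodes = np.searchsorted(
        np.sort(select(bundle, "ALL", "CA")),
        np.concatenate([select(bundle, "ICL3", "CA"),
                        select(bundle, "TM6_lower", "CA")]),
    )
    loop_matrix = region_overlap(result, protein_modes, np.unique(loop_nodes), k=k)
    np.savetxt(out / f"{chash}_loop_overlap_matrix.tsv", loop_matrix.values,
               header=f"config_hash={chash}\nregion-restricted O_ij, k={k}")

    # --- clustering -----------------------------------------------------
    assignment = rmsd_cluster(traj, config.cluster_fit_region,
                              config.cluster_measure_region,
                              config.cluster_cutoff)
    fractions_cluster = occupancy(assignment)
    np.savetxt(out / f"{chash}_clusters.tsv",
               np.column_stack([np.arange(traj.n_frames), traj.times,
                                assignment.labels]),
               header=f"config_hash={chash}\nframe\ttime_ns\tcluster",
               delimiter="\t", fmt=["%d", "%.4f", "%d"])
    write_trajectory(
        traj.with_frames(traj.frames[assignment.centroid_frames],
                         np.sort(traj.times[assignment.centroid_frames])),
        out / f"{chash}_cluster_centroids.pdb",
    )

    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "gpcrdyn_version": __version__,
        "numpy_version": np.__version__,
        "n_frames": traj.n_frames,
        "n_membrane_nodes": int((network.node_types == "membrane").sum()),
        "n_zero_modes_removed": anm_modes.n_zero_modes_removed,
        "variance_fraction_mode1": float(fractions[0]),
        "variance_fractions_top5": [float(f) for f in fractions[:5]],
        "average_overlap_k10": float(o_ave),
        "n_clusters": assignment.n_clusters,
        "cluster_occupancies": [float(f) for f in fractions_cluster],
        "loop_rmsd_step_A": float(np.mean(loop_prof.values[spec.transition_frame:])
                                  - np.mean(loop_prof.values[:spec.transition_frame])),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("pipeline summary: %s", summary)
    return summary
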