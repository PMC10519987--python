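"""Config-driven orchestration of the full contact and ensemble analyses.

The configuration defaults are the reference analysis parameters: 3.5 Å
contact cutoff, the last 300 ns of the trajectory at a 1 ns stride, a 10%
stable-pair threshold, 10 ns master-trajectory spacing, RMSD cutoffs
0.5–1.0 Å, a 2 nm separation denominator, a 5.65 Å NOE threshold and the
confidence parameters θ ∈ {10, 25}.

Report bundles are directories of TSV/JSON files plus a manifest that
echoes the configuration, seeds and input checksums; the manifest carries
no timestamps, so identical config+seed reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import contact_frequencies, interactivity_profile, partners_per_conformer
from .enrichment import (
    composition,
    contact_type_fractions,
    enrichment_table,
    heptad_position_matrix,
    shuffle_background,
)
from .ensemble import (
    ConformerEnsemble,
    NOERestraint,
    ObservableSet,
    maxent_reweight,
    noe_satisfaction,
    radius_of_gyration,
    rh_estimate,
    turn_fraction,
)
from .model import Trajectory, ValidationError
from .pairgeom import (
    build_master_trajectory,
    distance_distribution,
    gromos_cluster,
    occupancy_curve,
    stable_pairs,
)
from .sequence import annotate_heptads

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "ReportBundle", "run_contact_analysis", "run_ensemble_analysis"]


@dataclass
class AnalysisConfig:
    """All numeric knobs of the analysis; defaults are the reference values."""

    cutoff_A: float = 3.5
    window_ns: float = 300.0          # analysis window length, taken from the end
    stride_ps: float = 1000.0
    stable_threshold: float = 0.10
    master_spacing_ps: float = 10000.0
    rmsd_cutoffs: list = field(default_factory=lambda: [0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
    cluster_report_cutoff_A: float = 0.7
    separation_max_A: float = 20.0
    noe_threshold_A: float = 5.65
    noe_averaging: str = "r6"
    thetas: list = field(default_factory=lambda: [10.0, 25.0])
    seed: int = 0
    atom_filter: object = "all"
    min_seq_sep: int = 2
    heptad_register_offset: int = 0
    heptad_background: str = "position"
    shuffle_n: int = 1000
    hist_bin_width_A: float = 0.5
    # clustering cost is quadratic in configurations; larger masters are
    # evenly subsampled to this size before RMSD clustering (histograms
    # always use the full master)
    max_cluster_configurations: int = 400
    turn_motif: str = "SPSY"
    turn_cutoff_A: float = 5.0

    def __post_init__(self):
        for name in ("cutoff_A", "window_ns", "stride_ps", "master_spacing_ps",
                     "separation_max_A", "noe_threshold_A", "hist_bin_width_A",
                     "turn_cutoff_A"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.stable_threshold < 1:
            raise ValidationError("stable_threshold must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "atom_filter" in data and isinstance(data["atom_filter"], list):
            data["atom_filter"] = tuple(data["atom_filter"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["atom_filter"], tuple):
            d["atom_filter"] = list(d["atom_filter"])
        return d


@dataclass
class ReportBundle:
    outdir: Path
    manifest: dict

    def write_manifest(self) -> None:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @property
    def files(self) -> list[str]:
        return self.manifest.get("outputs", [])


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _analysis_window(trajectory: Trajectory, config: AnalysisConfig) -> tuple[float, float]:
    times = trajectory.times_ps
    end = float(times[-1])
    start = max(float(times[0]), end - config.window_ns * 1000.0)
    return start, end


def run_contact_analysis(
    trajectory: Trajectory,
    config: AnalysisConfig,
    outdir: str,
    input_path: Optional[str] = None,
) -> ReportBundle:
    """Contacts → enrichment → heptad matrix → stable pairs → master
    trajectory → clustering → distance distributions, in one bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    top = trajectory.topology
    outputs: list[str] = []
    notes: dict = {}

    def _register(name: str) -> Path:
        outputs.append(name)
        return out / name

    start, end = _analysis_window(trajectory, config)
    logger.info("analysis window %.0f-%.0f ps, stride %.0f ps", start, end, config.stride_ps)

    tables = {}
    for scope in ("intra", "inter"):
        if scope == "inter" and top.n_chains < 2:
            notes["inter"] = "skipped: single-chain system"
            continue
        stage = f"contacts[{scope}]"
        try:
            table = contact_frequencies(
                trajectory, start, end, config.stride_ps, scope=scope,
                cutoff_A=config.cutoff_A, min_seq_sep=config.min_seq_sep,
                atom_filter=config.atom_filter,
            )
        except Exception as exc:
            raise ValidationError(f"stage {stage} failed: {exc}") from exc
        tables[scope] = table
        table.to_tsv(_register(f"contacts_{scope}.tsv"), top)

    sequences = [c.sequence for c in top.chains]
    profile = composition(sequences)
    single = top.single_species()
    annotation = annotate_heptads(sequences[0], config.heptad_register_offset) if single else None

    for scope, table in tables.items():
        if not table.counts:
            notes[f"enrichment_{scope}"] = "skipped: no contacts"
            continue
        fractions, top10 = contact_type_fractions(table, top)
        top10.to_csv(_register(f"top10_{scope}.tsv"), sep="\t", index=False)
        enrichment_table(fractions, profile).to_csv(
            _register(f"enrichment_{scope}.tsv"), sep="\t", index=False)
        shuffle_background(
            table, top, n_shuffles=config.shuffle_n, seed=config.seed
        ).to_csv(_register(f"shuffle_background_{scope}.tsv"), sep="\t", index=False)
        if annotation is not None:
            try:
                hm = heptad_position_matrix(table, top, annotation, config.heptad_background)
                hm.to_dataframe().to_csv(_register(f"heptad_matrix_{scope}.tsv"), sep="\t")
            except ValidationError as exc:
                notes[f"heptad_{scope}"] = f"skipped: {exc}"

    if "inter" in tables and tables["inter"].counts and single:
        profile_inter = interactivity_profile(tables["inter"], top)
        pd.DataFrame(
            {"position": np.arange(1, profile_inter.values.size + 1),
             "interactivity": profile_inter.values}
        ).to_csv(_register("interactivity.tsv"), sep="\t", index=False)
        notes["partners_per_conformer"] = partners_per_conformer(tables["inter"], top)

    # stable pairs and pair geometry per scope
    pair_summary = {}
    for scope, table in tables.items():
        pairs = stable_pairs(table, config.stable_threshold)
        freqs = table.frequencies
        pd.DataFrame(
            [{"chain_a": k.chain_a, "res_a": k.res_a, "chain_b": k.chain_b,
              "res_b": k.res_b, "frequency": freqs[k]} for k in pairs]
        ).to_csv(_register(f"stable_pairs_{scope}.tsv"), sep="\t", index=False)
        if not pairs:
            notes[f"master_{scope}"] = "skipped: no stable pairs"
            continue
        # master trajectories pool one residue-type pair (Pro-Tyr when
        # present) so all configurations share an atom template
        by_type: dict[tuple, list] = {}
        for k in pairs:
            tp = tuple(sorted((top.residue(k.chain_a, k.res_a).name1,
                               top.residue(k.chain_b, k.res_b).name1)))
            by_type.setdefault(tp, []).append(k)
        py_pairs = by_type.get(("P", "Y"), [])
        if py_pairs:
            used = py_pairs
        else:
            tp_best = max(by_type, key=lambda tp: (len(by_type[tp]), tp))
            used = by_type[tp_best]
            notes[f"master_{scope}"] = (
                f"no Pro-Tyr stable pairs; pooled {tp_best[0]}-{tp_best[1]} pairs"
            )
        master = build_master_trajectory(
            trajectory, used, start, end + config.stride_ps,
            spacing_ps=config.master_spacing_ps,
        )
        hist = distance_distribution(master, config.hist_bin_width_A)
        pd.DataFrame(
            {"bin_left_A": hist.bin_edges[:-1], "bin_right_A": hist.bin_edges[1:],
             "density": hist.densities}
        ).to_csv(_register(f"pair_distance_hist_{scope}.tsv"), sep="\t", index=False)
        cluster_master = master
        if len(master) > config.max_cluster_configurations:
            pick = np.linspace(0, len(master) - 1,
                               config.max_cluster_configurations).astype(int)
            from .pairgeom import MasterTrajectory
            cluster_master = MasterTrajectory(
                configurations=[master.configurations[i] for i in pick],
                spacing_ps=master.spacing_ps, pairs=master.pairs)
            notes[f"cluster_subsample_{scope}"] = (
                f"clustered {len(pick)} of {len(master)} configurations (even grid)")
        near = [c for c in cluster_master.configurations
                if c.separation < config.separation_max_A]
        if near:
            curve = occupancy_curve(cluster_master, config.rmsd_cutoffs,
                                    config.separation_max_A)
            pd.DataFrame(curve, columns=["rmsd_cutoff_A", "top_cluster_population"]).to_csv(
                _register(f"occupancy_{scope}.tsv"), sep="\t", index=False)
            result = gromos_cluster(near, config.cluster_report_cutoff_A)
            _json_dump(
                {"rmsd_cutoff_A": result.rmsd_cutoff,
                 "n_configurations": len(near),
                 "clusters": result.clusters},
                _register(f"clusters_{scope}.json"),
            )
            pair_summary[scope] = {
                "n_stable_pairs": len(pairs),
                "n_pro_tyr_pairs": len(py_pairs),
                "n_configurations": len(master),
                "top_population_at_report_cutoff": result.top_population,
            }
        else:
            notes[f"clusters_{scope}"] = "skipped: no configurations below separation limit"

    manifest = {
        "tool": "ctdkit",
        "version": __version__,
        "analysis": "contacts",
        "config": config.to_dict(),
        "window_ps": [start, end],
        "input_sha256": _sha256(input_path) if input_path else None,
        "n_frames": trajectory.n_frames,
        "n_chains": top.n_chains,
        "pair_summary": pair_summary,
        "notes": notes,
        "outputs": sorted(outputs),
    }
    bundle = ReportBundle(outdir=out, manifest=manifest)
    bundle.write_manifest()
    return bundle


def run_ensemble_analysis(
    ensemble: ConformerEnsemble,
    config: AnalysisConfig,
    outdir: str,
    observables: Optional[ObservableSet] = None,
    restraints: Optional[Sequence[NOERestraint]] = None,
    input_path: Optional[str] = None,
) -> ReportBundle:
    """Turn fractions, NOE satisfaction, R_g/R_h and θ-grid reweighting."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    top = ensemble.trajectory.topology
    outputs: list[str] = []
    notes: dict = {}

    def _register(name: str) -> Path:
        outputs.append(name)
        return out / name

    # backbone turns at every occurrence of the turn motif
    quadruplets = []
    for chain in top.chains:
        seq = chain.sequence
        for s in range(len(seq) - len(config.turn_motif) + 1):
            if seq[s:s + len(config.turn_motif)] == config.turn_motif:
                quadruplets.append((chain.chain_id, chain.residues[s].index))
    if quadruplets:
        frac, per_window = turn_fraction(ensemble, quadruplets, config.turn_cutoff_A)
        _json_dump(
            {"motif": config.turn_motif, "cutoff_A": config.turn_cutoff_A,
             "conformer_fraction": frac,
             "per_window": {f"{c}:{r}": v for (c, r), v in per_window.items()}},
            _register("turns.json"),
        )
    else:
        notes["turns"] = f"skipped: motif {config.turn_motif!r} not found"

    rows = []
    for k, frame in enumerate(ensemble.trajectory.frames):
        rows.append(
            {"conformer": k,
             "Rg_A": radius_of_gyration(frame),
             "Rh_A": rh_estimate(frame, top)}
        )
    pd.DataFrame(rows).to_csv(_register("rg_rh.tsv"), sep="\t", index=False)

    if restraints:
        matched, report = noe_satisfaction(
            ensemble, restraints, threshold_A=config.noe_threshold_A,
            averaging=config.noe_averaging,
        )
        report.to_csv(_register("noe_report.tsv"), sep="\t", index=False)
        notes["noe_matched"] = f"{matched}/{len(restraints)}"

    if observables is not None:
        reweight_rows = []
        for theta in config.thetas:
            result = maxent_reweight(observables, theta=theta,
                                     w0=ensemble.reference_weights)
            _json_dump(result.to_dict(), _register(f"reweight_theta{theta:g}.json"))
            reweight_rows.append(
                {"theta": theta, "chi2": result.chi2, "skl": result.skl}
            )
        pd.DataFrame(reweight_rows).to_csv(_register("reweight_summary.tsv"),
                                           sep="\t", index=False)

    manifest = {
        "tool": "ctdkit",
        "version": __version__,
        "analysis": "ensemble",
        "config": config.to_dict(),
        "input_sha256": _sha256(input_path) if input_path else None,
        "n_conformers": ensemble.n_conformers,
        "notes": notes,
        "outputs": sorted(outputs),
    }
    bundle = ReportBundle(outdir=out, manifest=manifest)
    bundle.write_manifest()
    return bundle
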