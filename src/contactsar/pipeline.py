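"""End-to-end orchestration: contacts -> occupancy -> PLS -> reports.

A single :class:`PipelineConfig` holds every tunable (candidate cutoff,
stride, per-type occupancy cutoffs, replicate policy, PLS settings); the
run writes deterministic CSV/JSON artifacts plus a provenance report with
the config hash, library versions, defaults actually used and any
warnings (e.g. the small-sample warning for studies with few ligands,
where the PLS model is severely underdetermined and coefficient values —
though not necessarily their signs — are fragile).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem import monoisotopic_mass, parse_formula, read_ligand_table
from .contacts import (
    DEFAULT_OCCUPANCY_CUTOFFS,
    ContactSet,
    collapse_equivalents,
    contact_set_to_frame,
    enumerate_candidates,
    filter_contacts,
)
from .occupancy import build_matrix, distance_timeseries, occupancy_percent, smooth_series
from .pls import coefficients_frame, fit_pls, weights_frame
from .structure import Topology, annotate_groups, read_topology, read_trajectory

__all__ = [
    "PipelineConfig",
    "run_all",
    "analyze_trajectories",
    "masscheck",
    "SMALL_N_THRESHOLD",
]

#: Below this many ligand rows the PLS fit is flagged as underdetermined.
SMALL_N_THRESHOLD = 6


@dataclass
class PipelineConfig:
    topology: str
    trajectories: list  # of {"ligand": ..., "replicate": ..., "path": ...}
    ligand_table: str
    outdir: str = "out"
    ligand_resname: Optional[str] = None
    ligand_carboxylates: list = field(default_factory=list)
    ligand_rings: list = field(default_factory=list)
    candidate_cutoff: float = 4.0
    stride: int = 1
    hbond_elements: list = field(default_factory=lambda: ["N", "O", "S"])
    ring_candidate_cutoff: float = 6.0
    occupancy_cutoffs: dict = field(
        default_factory=lambda: dict(DEFAULT_OCCUPANCY_CUTOFFS)
    )
    replicate_policy: str = "mean"
    n_components: Optional[int] = None
    scale: bool = True
    smoothing_window: int = 51
    plot_coef_threshold: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.candidate_cutoff <= 0 or self.ring_candidate_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if any(v <= 0 for v in self.occupancy_cutoffs.values()):
            raise ValueError("occupancy cutoffs must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """An identified pipeline stage failed on an identified input."""


def _stage(name: str, detail: str, exc: Exception) -> StageError:
    return StageError(f"stage {name!r} failed on {detail}: {exc}")


def _load_inputs(config: PipelineConfig):
    base = Path(config.topology).parent
    try:
        topo = read_topology(
            Path(config.topology).read_text(), ligand_resname=config.ligand_resname
        )
        topo = annotate_groups(
            topo,
            ligand_carboxylates=config.ligand_carboxylates,
            ligand_rings=config.ligand_rings,
        )
    except Exception as exc:
        raise _stage("topology", config.topology, exc) from exc
    trajs = {}
    for entry in config.trajectories:
        lig, rep = str(entry["ligand"]), str(entry["replicate"])
        path = Path(entry["path"])
        if not path.is_absolute():
            path = base / path
        try:
            trajs[(lig, rep)] = read_trajectory(
                path.read_text(), topo, replicate_id=f"{lig}_{rep}"
            )
        except Exception as exc:
            raise _stage("trajectory", str(path), exc) from exc
    return topo, trajs


def _contacts_for_ligand(config, topo, ligand_trajs) -> ContactSet:
    pairs = set()
    ring_pairs = []
    seen_rings = set()
    for traj in ligand_trajs:
        p = enumerate_candidates(
            traj, topo, candidate_cutoff=config.candidate_cutoff, stride=config.stride
        )
        kept, rings = filter_contacts(
            p,
            topo,
            traj,
            hbond_elements=config.hbond_elements,
            ring_candidate_cutoff=config.ring_candidate_cutoff,
            stride=config.stride,
        )
        pairs.update(kept)
        for lr, rr in rings:
            key = (tuple(sorted(lr.atom_indices)), tuple(sorted(rr.atom_indices)))
            if key not in seen_rings:
                seen_rings.add(key)
                ring_pairs.append((lr, rr))
    ordered = sorted(pairs, key=lambda pr: (pr[1], pr[0]))
    return collapse_equivalents(
        ordered,
        topo,
        ring_pairs=ring_pairs,
        cutoffs=config.occupancy_cutoffs,
        provenance={
            "candidate_cutoff": config.candidate_cutoff,
            "stride": config.stride,
        },
    )


def run_all(config: PipelineConfig) -> dict:
    """Execute contacts -> occupancy -> PLS and write all artifacts.

    Returns the run report (also written as ``run_report.json``).
    Warnings never abort; stage errors abort naming the stage and input.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    topo, trajs = _load_inputs(config)
    ligand_order: list[str] = []
    for lig, _ in trajs:
        if lig not in ligand_order:
            ligand_order.append(lig)

    # --- contacts -----------------------------------------------------
    contact_sets: dict[str, ContactSet] = {}
    for lig in ligand_order:
        ligand_trajs = [t for (l, _), t in trajs.items() if l == lig]
        try:
            contact_sets[lig] = _contacts_for_ligand(config, topo, ligand_trajs)
        except Exception as exc:
            raise _stage("contacts", f"ligand {lig!r}", exc) from exc
    union: dict[str, object] = {}
    for lig in ligand_order:
        for c in contact_sets[lig]:
            union.setdefault(c.contact_id, c)
    union_contacts = sorted(
        union.values(), key=lambda c: (c.residue_number, c.ligand_order, c.contact_id)
    )
    contacts_df = contact_set_to_frame(ContactSet(contacts=list(union_contacts)))
    contacts_df.to_csv(outdir / "contacts.csv", index=False)

    # --- occupancy ----------------------------------------------------
    series_cache = {}
    entries = []
    summary_rows = []
    for (lig, rep), traj in trajs.items():
        occ = {}
        for c in contact_sets[lig]:
            try:
                ts = distance_timeseries(traj, topo, c)
            except Exception as exc:
                raise _stage("occupancy", f"contact {c.contact_id!r} on {lig}/{rep}", exc) from exc
            series_cache[(lig, rep, c.contact_id)] = ts
            occ[c.contact_id] = occupancy_percent(ts)
            summary_rows.append(
                {
                    "ligand_id": lig,
                    "replicate_id": rep,
                    "contact_id": c.contact_id,
                    "occupancy_pct": occ[c.contact_id],
                    "mean_distance": float(ts.distances.mean()),
                    "min_distance": float(ts.distances.min()),
                    "max_distance": float(ts.distances.max()),
                }
            )
        entries.append((lig, rep, occ))
    contact_ids = [c.contact_id for c in union_contacts]
    matrix = build_matrix(entries, contact_ids, policy=config.replicate_policy)
    matrix.to_dataframe().to_csv(outdir / "occupancy_matrix.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(outdir / "timeseries_summary.csv", index=False)

    # --- response -----------------------------------------------------
    records = {r.ligand_id: r for r in read_ligand_table(Path(config.ligand_table))}
    missing = [lig for lig in matrix.ligand_ids if lig not in records or records[lig].pic50 is None]
    if missing:
        raise _stage("pls", f"ligands without potency: {missing}", ValueError("missing IC50"))
    y = np.array([records[lig].pic50 for lig in matrix.ligand_ids])

    n_rows = len(matrix.ligand_ids)
    if len(set(matrix.ligand_ids)) < SMALL_N_THRESHOLD:
        warnings_log.append(
            f"small-n: only {len(set(matrix.ligand_ids))} ligands; the PLS model is "
            "severely underdetermined and coefficients are fragile"
        )

    # --- PLS ----------------------------------------------------------
    n_comp = config.n_components
    if n_comp is None:
        n_comp = min(2, n_rows - 1)
    try:
        model = fit_pls(matrix, y, n_components=n_comp, scale=config.scale)
    except Exception as exc:
        raise _stage("pls", "occupancy matrix", exc) from exc
    weights_frame(model).to_csv(outdir / "pls_weights.csv", index=False)
    coefficients_frame(model).to_csv(outdir / "pls_coefficients.csv", index=False)

    # --- smoothed-trend plot data for the strongest contacts ----------
    strong = [
        cid
        for cid, b in zip(model.contact_ids, model.beta_standardized)
        if abs(b) > config.plot_coef_threshold
    ]
    plot_data = {}
    for cid in strong:
        per_series = []
        for (lig, rep, c), ts in series_cache.items():
            if c != cid:
                continue
            window = min(config.smoothing_window, ts.n_frames)
            trend, band = smooth_series(ts, window)
            step = max(1, ts.n_frames // 400)
            per_series.append(
                {
                    "ligand": lig,
                    "replicate": rep,
                    "frame": list(range(0, ts.n_frames, step)),
                    "trend": np.round(trend[::step], 3).tolist(),
                    "band": np.round(band[::step], 3).tolist(),
                    "cutoff": ts.cutoff,
                }
            )
        plot_data[cid] = per_series
    (outdir / "plot_data.json").write_text(json.dumps(plot_data, sort_keys=True))

    report = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_ligands": len(set(matrix.ligand_ids)),
        "n_rows": n_rows,
        "n_contacts": len(contact_ids),
        "n_components": model.n_components,
        "replicate_policy": config.replicate_policy,
        "defaults_used": {
            "occupancy_cutoffs": dict(config.occupancy_cutoffs),
            "candidate_cutoff": config.candidate_cutoff,
            "ring_candidate_cutoff": config.ring_candidate_cutoff,
            "hbond_elements": list(config.hbond_elements),
            "stride": config.stride,
            "tie_rule": "distance equal to cutoff counts as in-contact",
            "replicate_policy": config.replicate_policy,
            "autoscale_x": config.scale,
            "fluctuation_band": "rolling population sd, centred window",
            "response": "pIC50 from the ligand table IC50 column",
        },
        "warnings": warnings_log,
        "artifacts": [
            "contacts.csv",
            "occupancy_matrix.csv",
            "timeseries_summary.csv",
            "pls_weights.csv",
            "pls_coefficients.csv",
            "plot_data.json",
            "run_report.json",
        ],
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def analyze_trajectories(
    topo: Topology,
    trajectories: dict,
    pic50_by_ligand: dict,
    config: Optional[PipelineConfig] = None,
):
    """Run contacts -> occupancy -> PLS on in-memory trajectories.

    ``trajectories`` maps (ligand_id, replicate_id) to a Trajectory; the
    topology must already carry group/ring annotations.  Returns
    ``(matrix, model)``.  This is the same analysis chain as
    :func:`run_all` without file artifacts.
    """
    if config is None:
        config = PipelineConfig(topology="", trajectories=[], ligand_table="")
    ligand_order: list[str] = []
    for lig, _ in trajectories:
        if lig not in ligand_order:
            ligand_order.append(lig)
    contact_sets = {
        lig: _contacts_for_ligand(
            config, topo, [t for (l, _), t in trajectories.items() if l == lig]
        )
        for lig in ligand_order
    }
    union: dict[str, object] = {}
    for lig in ligand_order:
        for c in contact_sets[lig]:
            union.setdefault(c.contact_id, c)
    union_contacts = sorted(
        union.values(), key=lambda c: (c.residue_number, c.ligand_order, c.contact_id)
    )
    entries = []
    for (lig, rep), traj in trajectories.items():
        occ = {
            c.contact_id: occupancy_percent(distance_timeseries(traj, topo, c))
            for c in contact_sets[lig]
        }
        entries.append((lig, rep, occ))
    matrix = build_matrix(
        entries, [c.contact_id for c in union_contacts], policy=config.replicate_policy
    )
    y = np.array([pic50_by_ligand[lig] for lig in matrix.ligand_ids])
    n_comp = config.n_components
    if n_comp is None:
        n_comp = min(2, len(matrix.ligand_ids) - 1)
    model = fit_pls(matrix, y, n_components=n_comp, scale=config.scale)
    return matrix, model


def masscheck(
    ligand_table_path, expected_column: str = "expected_mplus_h", tol: float = 0.0005
) -> pd.DataFrame:
    """Compute [M+H]+ monoisotopic masses and pIC50s for a ligand table.

    Unparseable formulas produce a per-row error note; the run continues.
    If the table carries an expected-mass column, rows deviating beyond
    ``tol`` Da are flagged.
    """
    raw = pd.read_csv(ligand_table_path, dtype={"ligand_id": str, "formula": str})
    rows = []
    for _, r in raw.iterrows():
        row = {"ligand_id": r["ligand_id"], "formula": r.get("formula", ""), "note": ""}
        formula_text = r.get("formula")
        if not isinstance(formula_text, str) or not formula_text.strip():
            row["note"] = "skipped: empty formula"
            row["monoisotopic_mass_mplus_h"] = np.nan
        else:
            try:
                row["monoisotopic_mass_mplus_h"] = monoisotopic_mass(
                    parse_formula(formula_text.strip())
                )
            except Exception as exc:
                row["monoisotopic_mass_mplus_h"] = np.nan
                row["note"] = f"error: {exc}"
        ic50 = r.get("ic50_nM")
        row["pic50"] = (
            -np.log10(float(ic50) * 1e-9) if pd.notna(ic50) and float(ic50) > 0 else np.nan
        )
        if expected_column in raw.columns and pd.notna(r.get(expected_column)):
            expected = float(r[expected_column])
            got = row["monoisotopic_mass_mplus_h"]
            if pd.isna(got) or abs(got - expected) > tol:
                row["note"] = (row["note"] + "; " if row["note"] else "") + (
                    f"mass mismatch: computed {got} vs expected {expected}"
                )
        rows.append(row)
    return pd.DataFrame(rows)
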