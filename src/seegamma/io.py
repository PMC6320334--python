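"""Plain-text / container IO: trial tables (CSV), meshes (OFF), lead maps
(CSV), classification tables (CSV) and whole-cohort array stores (NPZ +
JSON sidecar for the ground truth)."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GroundTruth, SyntheticCohort
from .types import (
    LeadRecord,
    LeadTimeCourses,
    ToyMesh,
    TrialRecord,
    STIMULUS_FACTORS,
    trials_to_frame,
)


def write_trials_csv(trials: list[TrialRecord], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials_csv(path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        factors = {k: bool(r[f"factor_{k}"]) for k in STIMULUS_FACTORS
                   if f"factor_{k}" in r and pd.notna(r[f"factor_{k}"])}
        out.append(TrialRecord(
            trial_id=int(r["trial_id"]), subject=str(r["subject"]),
            task=str(r["task"]), length=str(r["length"]),
            block=int(r["block"]), static_duration=int(r["static_duration"]),
            video_duration=float(r["video_duration"]),
            truncation_offset=(None if pd.isna(r["truncation_offset"])
                               else float(r["truncation_offset"])),
            factors=factors,
            rt=None if pd.isna(r["rt"]) else float(r["rt"]),
            correct=None if pd.isna(r["correct"]) else bool(r["correct"]),
            ied_flag=bool(r["ied_flag"])))
    return out


def write_mesh_off(mesh: ToyMesh, path) -> None:
    """OFF-style plain-text triangle mesh."""
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_nodes} {len(mesh.triangles)} 0\n")
        for x, y, z in mesh.nodes:
            fh.write(f"{x:.6g} {y:.6g} {z:.6g}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")


def read_mesh_off(path) -> ToyMesh:
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip()]
    if lines[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf, _ = map(int, lines[1].split())
    nodes = np.array([[float(x) for x in l.split()] for l in lines[2:2 + nv]])
    tris = np.array([[int(x) for x in l.split()[1:4]]
                     for l in lines[2 + nv:2 + nv + nf]], dtype=int)
    return ToyMesh(nodes=nodes, triangles=tris)


def write_lead_map_csv(leads: list[LeadRecord], path) -> None:
    pd.DataFrame([{
        "lead_id": l.lead_id, "subject": l.subject,
        "hemisphere": l.hemisphere, "region": l.region,
        "true_class": l.true_class,
        "node_ids": (" ".join(map(str, l.node_ids))
                     if l.node_ids is not None else ""),
    } for l in leads]).to_csv(path, index=False)


def surface_map_csv(values: np.ndarray, mask: np.ndarray, path) -> None:
    pd.DataFrame({"node": np.arange(len(values)), "value": values,
                  "masked": mask}).to_csv(path, index=False)


def save_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Array store (NPZ keyed by lead) + JSON ground-truth sidecar + CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_trials = [t for s in cohort.subjects for t in cohort.trials[s]]
    # trial ids are unique per subject only; store per subject
    for s in cohort.subjects:
        write_trials_csv(cohort.trials[s], out / f"trials_{s}.csv")
    write_lead_map_csv(cohort.leads, out / "leads.csv")
    if cohort.mesh is not None:
        write_mesh_off(cohort.mesh, out / "mesh.off")
    arrays = {}
    meta = {}
    for lid, tc in cohort.timecourses.items():
        arrays[f"values__{lid}"] = tc.values
        arrays[f"trials__{lid}"] = tc.trial_ids
        meta[lid] = {"bin_ms": tc.bin_ms, "t0_offset_ms": tc.t0_offset_ms,
                     "lead_class": tc.truth.get("lead_class"),
                     "hemisphere": tc.truth.get("hemisphere"),
                     "subject_onset_ms": tc.truth.get("subject_onset_ms"),
                     "subject_duration_ms": tc.truth.get("subject_duration_ms")}
    np.savez_compressed(out / "timecourses.npz", **arrays)
    truth_d = dataclasses.asdict(cohort.truth)
    # accuracy is keyed by (length, task) tuples; JSON needs string keys
    truth_d["accuracy"] = {"|".join(k): v
                           for k, v in truth_d["accuracy"].items()}
    sidecar = {
        "truth": truth_d,
        "subjects": cohort.subjects,
        "subject_onsets": cohort.subject_onsets,
        "leads_meta": meta,
    }
    (out / "ground_truth.json").write_text(
        json.dumps(sidecar, indent=1, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_cohort(in_dir) -> SyntheticCohort:
    src = Path(in_dir)
    sidecar = json.loads((src / "ground_truth.json").read_text())
    truth_d = sidecar["truth"]
    truth_d["accuracy"] = {tuple(k.split("|")): v
                           for k, v in truth_d["accuracy"].items()}
    truth = GroundTruth(**truth_d)
    subjects = sidecar["subjects"]
    trials = {s: read_trials_csv(src / f"trials_{s}.csv") for s in subjects}
    leads_df = pd.read_csv(src / "leads.csv")
    leads = [LeadRecord(
        lead_id=r["lead_id"], subject=r["subject"],
        hemisphere=r["hemisphere"], region=r["region"],
        true_class=None if pd.isna(r["true_class"]) else r["true_class"],
        node_ids=(np.array([int(x) for x in str(r["node_ids"]).split()])
                  if isinstance(r["node_ids"], str) and r["node_ids"].strip()
                  else None))
        for _, r in leads_df.iterrows()]
    mesh = read_mesh_off(src / "mesh.off") if (src / "mesh.off").exists() else None
    npz = np.load(src / "timecourses.npz")
    tcs = {}
    for lid, m in sidecar["leads_meta"].items():
        tcs[lid] = LeadTimeCourses(
            values=npz[f"values__{lid}"], bin_ms=m["bin_ms"],
            t0_offset_ms=m["t0_offset_ms"], lead_id=lid,
            trial_ids=npz[f"trials__{lid}"],
            truth={k: m[k] for k in ("lead_class", "hemisphere",
                                     "subject_onset_ms",
                                     "subject_duration_ms")})
    return SyntheticCohort(subjects=subjects, trials=trials, leads=leads,
                           timecourses=tcs, mesh=mesh, truth=truth,
                           subject_onsets=sidecar["subject_onsets"])


__all__ = [
    "load_cohort", "read_mesh_off", "read_trials_csv", "save_cohort",
    "surface_map_csv", "write_lead_map_csv", "write_mesh_off",
    "write_trials_csv",
]
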