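"""On-disk cohort I/O: read the layout produced by ``write_cohort`` (or an
equivalently organized export of real data) back into in-memory patients.

Expected layout::

    DIR/
      lab.csv vital.csv medication.csv   # long-format event tables
      visits.csv                         # patient_id, visit_time, edss
      demographics.csv                   # patient_id, race, ethnicity, sex, age
      notes/*.txt + notes_manifest.csv   # patient_id, encounter_id, path
      images/*.nii.gz + image_manifest.csv  # patient_id, session_time, sequence, path
      spec.json                          # generator parameters (optional)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SignalSpec, SyntheticCohort, SyntheticPatient

__all__ = ["load_cohort"]

_EVENT_COLS = ["encounter_id", "encounter_start", "encounter_end",
               "obs_time", "feature", "value"]


def load_cohort(directory: str | Path) -> SyntheticCohort:
    """Load a cohort directory into a :class:`SyntheticCohort`.

    Labels are not read from disk: they are re-derived downstream from the
    EDSS trajectories, so external cohorts only need the tables above.
    """
    d = Path(directory)
    events = {}
    for kind in ("lab", "vital", "medication"):
        df = pd.read_csv(d / f"{kind}.csv",
                         parse_dates=["encounter_start", "encounter_end",
                                      "obs_time"])
        events[kind] = df
    visits = pd.read_csv(d / "visits.csv", parse_dates=["visit_time"])
    demo = pd.read_csv(d / "demographics.csv").set_index("patient_id")

    notes_by_pid: dict[str, list[tuple[str, str]]] = {}
    manifest = d / "notes_manifest.csv"
    if manifest.exists():
        for row in pd.read_csv(manifest).itertuples(index=False):
            text = (d / row.path).read_text(encoding="utf-8")
            notes_by_pid.setdefault(row.patient_id, []).append(
                (row.encounter_id, text))

    sessions_by_pid: dict[str, dict] = {}
    manifest = d / "image_manifest.csv"
    if manifest.exists():
        import nibabel as nib

        img = pd.read_csv(manifest, parse_dates=["session_time"])
        for row in img.itertuples(index=False):
            key = (row.patient_id, row.session_time)
            sess = sessions_by_pid.setdefault(row.patient_id, {}).setdefault(
                key, {"time": row.session_time.to_pydatetime(),
                      "volumes": {}, "blobs": {}})
            sess["volumes"][row.sequence] = np.asarray(
                nib.load(d / row.path).get_fdata(), dtype=np.float32)

    spec_file = d / "spec.json"
    if spec_file.exists():
        raw = json.loads(spec_file.read_text())
        raw["sequences"] = tuple(raw.get("sequences", ()))
        raw["volume_shape"] = tuple(raw.get("volume_shape", (32, 32, 32)))
        spec = SignalSpec(**raw)
    else:
        spec = SignalSpec(n_patients=demo.shape[0])

    patients = []
    for pid in demo.index:
        p_events = {
            kind: df[df.patient_id == pid][_EVENT_COLS].reset_index(drop=True)
            for kind, df in events.items()
        }
        p_visits = (visits[visits.patient_id == pid]
                    [["visit_time", "edss"]].reset_index(drop=True))
        last_edss = float(p_visits.sort_values("visit_time").edss.iloc[-1])
        patients.append(SyntheticPatient(
            patient_id=pid,
            label=int(last_edss > spec.milestone),
            events=p_events,
            visits=p_visits,
            demographics=demo.loc[pid].to_dict(),
            sessions=list(sessions_by_pid.get(pid, {}).values()),
            notes=notes_by_pid.get(pid, []),
        ))
    return SyntheticCohort(spec=spec, patients=patients)
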