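"""Plain-text I/O for every artifact the pipeline produces.

Formats:

- ECG: two-column CSV ``time_s,voltage_mv``;
- beat times: single-column CSV ``time_s``;
- RR series: one interval in ms per line (anchors rebuilt by cumulative sum);
- stimulus schedules: CSV ``onset_s,duration_s,general_class,subclass``;
- HRV features: tidy CSV ``segment,feature,value,unit,flagged``;
- class hierarchy + cost scheme: YAML (or JSON) config;
- evaluation reports and study manifests: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BeatTimes, EcgRecord, RrSeries
from .evaluate import ClassHierarchy, CostScheme, EvaluationReport
from .hrv import HrvFeatureVector
from .schedule import Epoch, StimulusSchedule

__all__ = [
    "write_ecg_csv", "read_ecg_csv",
    "write_beats_csv", "read_beats_csv",
    "write_rr_text", "read_rr_text",
    "write_schedule_csv", "read_schedule_csv",
    "write_features_csv",
    "load_hierarchy_config", "write_hierarchy_config",
    "write_report_json",
    "write_study",
]


def write_ecg_csv(record: EcgRecord, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": record.times_s, "voltage_mv": record.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def read_ecg_csv(path: str | Path) -> EcgRecord:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-3):
        raise ValueError("ECG CSV is not uniformly sampled")
    return EcgRecord(df["voltage_mv"].to_numpy(), 1.0 / float(np.mean(dt)), float(t[0]))


def write_beats_csv(beats: BeatTimes, path: str | Path) -> None:
    pd.DataFrame({"time_s": beats.times_s}).to_csv(path, index=False, float_format="%.6f")


def read_beats_csv(path: str | Path) -> BeatTimes:
    return BeatTimes(pd.read_csv(path)["time_s"].to_numpy())


def write_rr_text(rr: RrSeries, path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(f"{v:.6f}" for v in rr.intervals_ms) + "\n"
    )


def read_rr_text(path: str | Path) -> RrSeries:
    values = [float(line) for line in Path(path).read_text().split() if line.strip()]
    return RrSeries(np.asarray(values))


def write_schedule_csv(schedule: StimulusSchedule, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "onset_s": e.onset_s,
                "duration_s": e.duration_s,
                "general_class": e.general_class,
                "subclass": e.subclass,
            }
            for e in schedule
        ]
    )
    df.to_csv(path, index=False)


def read_schedule_csv(path: str | Path) -> StimulusSchedule:
    df = pd.read_csv(path)
    return StimulusSchedule(
        Epoch(float(r.onset_s), float(r.duration_s), str(r.general_class), str(r.subclass))
        for r in df.itertuples()
    )


def write_features_csv(
    features: dict[str, HrvFeatureVector], path: str | Path
) -> None:
    """Tidy per-segment feature table: segment x feature x value x unit x flag."""
    rows = []
    for seg_id, fv in features.items():
        for name, value in fv.values.items():
            rows.append(
                {
                    "segment": seg_id,
                    "feature": name,
                    "value": value,
                    "unit": fv.units.get(name, ""),
                    "flagged": name in fv.flags,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_hierarchy_config(path: str | Path) -> tuple[ClassHierarchy, CostScheme]:
    """Read a hierarchy + cost-scheme config (YAML or JSON).

    Layout::

        general_classes:
          - name: consonant
            subclasses: [unison, fifth, fourth]
          - name: dissonant
            subclasses: [tritone, minor_second]
        scheme:
          kind: gompertz
          beta: 1.0
          gamma: 1.0
          C: 1.0
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    groups = [(g["name"], list(g["subclasses"])) for g in data["general_classes"]]
    sch = data.get("scheme", {})
    scheme = CostScheme(
        kind=sch.get("kind", "gompertz"),
        beta=float(sch.get("beta", 1.0)),
        gamma=float(sch.get("gamma", 1.0)),
        C=float(sch.get("C", 1.0)),
    )
    return ClassHierarchy(groups), scheme


def write_hierarchy_config(
    hierarchy: ClassHierarchy, scheme: CostScheme, path: str | Path
) -> None:
    data = {
        "general_classes": [
            {"name": name, "subclasses": list(subs)}
            for name, subs in hierarchy.groups
        ],
        "scheme": {
            "kind": scheme.kind,
            "beta": scheme.beta,
            "gamma": scheme.gamma,
            "C": scheme.C,
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_report_json(report: EvaluationReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def write_study(study, out_dir: str | Path) -> Path:
    """Persist a synthetic study: per-subject ECG/RR/schedule plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "hierarchy": [
            {"name": name, "subclasses": list(subs)}
            for name, subs in study.hierarchy.groups
        ],
        "records": [],
    }
    for rec in study.records:
        entry = {"subject_id": rec.subject_id}
        rr_path = out / f"{rec.subject_id}_rr.txt"
        write_rr_text(rec.rr_truth, rr_path)
        entry["rr"] = rr_path.name
        sched_path = out / f"{rec.subject_id}_schedule.csv"
        write_schedule_csv(rec.schedule, sched_path)
        entry["schedule"] = sched_path.name
        if rec.ecg is not None:
            ecg_path = out / f"{rec.subject_id}_ecg.csv"
            write_ecg_csv(rec.ecg.record, ecg_path)
            entry["ecg"] = ecg_path.name
        manifest["records"].append(entry)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path
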