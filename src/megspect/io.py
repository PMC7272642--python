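"""On-disk formats: HDF5 cohorts/recordings, TSV tables, JSON reports.

Recordings live in HDF5 with a dataset ``data`` (channels x samples,
float64, tesla), attributes ``sampling_rate``, ``subject_id`` and
``condition``, and a ``channels`` table (id, position, orientation).  A
cohort file holds one group per subject x condition under ``/subjects``
plus the head-model geometry under ``/geometry``.  Tabular outputs are
TSV with a fixed float format so that identical runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preproc import EpochSet, RawRecording
from .synth import Cohort, CohortSpec, HeadModelGeometry, SensorArrayGeometry
from .sourceest import LeadFieldMatrix

FLOAT_FORMAT = "%.12g"


def _write_channels(parent: h5py.Group, sensors: SensorArrayGeometry) -> None:
    g = parent.create_group("channels")
    g.create_dataset("id", data=np.array(sensors.channel_ids, dtype="S"))
    g.create_dataset("position", data=sensors.positions)
    g.create_dataset("orientation", data=sensors.orientations)


def _read_channels(parent: h5py.Group) -> SensorArrayGeometry:
    g = parent["channels"]
    return SensorArrayGeometry(
        channel_ids=tuple(s.decode() for s in g["id"][()]),
        positions=g["position"][()],
        orientations=g["orientation"][()],
    )


def _write_geometry(parent: h5py.Group, head: HeadModelGeometry) -> None:
    g = parent.create_group("geometry")
    g.attrs["sphere_radius"] = head.sphere_radius
    g.create_dataset("sphere_center", data=head.sphere_center)
    g.create_dataset("vertices", data=head.vertices)
    g.create_dataset("normals", data=head.normals)
    g.create_dataset("region_names", data=np.array(head.region_names, dtype="S"))
    g.create_dataset("vertex_region", data=head.vertex_region)


def _read_geometry(parent: h5py.Group) -> HeadModelGeometry:
    g = parent["geometry"]
    return HeadModelGeometry(
        sphere_center=g["sphere_center"][()],
        sphere_radius=float(g.attrs["sphere_radius"]),
        vertices=g["vertices"][()],
        normals=g["normals"][()],
        region_names=tuple(s.decode() for s in g["region_names"][()]),
        vertex_region=g["vertex_region"][()],
    )


def _write_recording(parent: h5py.Group, rec: RawRecording) -> None:
    d = parent.create_dataset("data", data=rec.values)
    d.attrs["sampling_rate"] = rec.sampling_rate
    d.attrs["subject_id"] = rec.subject_id
    d.attrs["condition"] = rec.condition


def _read_recording(parent: h5py.Group) -> RawRecording:
    d = parent["data"]
    return RawRecording(
        values=d[()],
        sampling_rate=float(d.attrs["sampling_rate"]),
        subject_id=str(d.attrs.get("subject_id", "")),
        condition=str(d.attrs.get("condition", "")),
    )


def save_cohort(path: str | Path, cohort: Cohort) -> None:
    """Write a cohort (recordings, geometry, channels, truth) to HDF5."""
    with h5py.File(path, "w") as f:
        _write_channels(f, cohort.sensors)
        _write_geometry(f, cohort.head)
        f.create_dataset("leadfield", data=cohort.leadfield.values)
        subs = f.create_group("subjects")
        for (sid, cond), rec in cohort.recordings.items():
            _write_recording(subs.create_group(f"{sid}/{cond}"), rec)
        meta = f.create_group("meta")
        meta.attrs["subject_ids"] = json.dumps(
            list(cohort.subjects["subject_id"])
        )
        meta.attrs["groups"] = json.dumps(list(cohort.subjects["group"]))
        meta.attrs["spec"] = json.dumps(
            {
                k: v
                for k, v in vars(cohort.spec).items()
                if k != "amplitude_table"
            }
        )
        if cohort.true_amplitudes is not None:
            t = cohort.true_amplitudes
            tg = f.create_group("truth")
            for col in ("subject_id", "group", "condition", "band", "region"):
                tg.create_dataset(col, data=np.array(t[col], dtype="S"))
            tg.create_dataset("amplitude", data=t["amplitude"].to_numpy())


def load_cohort(path: str | Path) -> Cohort:
    """Read a cohort HDF5 file written by :func:`save_cohort`."""
    with h5py.File(path, "r") as f:
        sensors = _read_channels(f)
        head = _read_geometry(f)
        leadfield = LeadFieldMatrix(values=f["leadfield"][()])
        meta = f["meta"]
        ids = json.loads(meta.attrs["subject_ids"])
        groups = json.loads(meta.attrs["groups"])
        spec_kw = json.loads(meta.attrs["spec"])
        cohort = Cohort(
            spec=CohortSpec(**spec_kw),
            sensors=sensors,
            head=head,
            leadfield=leadfield,
            subjects=pd.DataFrame({"subject_id": ids, "group": groups}),
        )
        for sid in f["subjects"]:
            for cond in f[f"subjects/{sid}"]:
                cohort.recordings[(sid, cond)] = _read_recording(
                    f[f"subjects/{sid}/{cond}"]
                )
        if "truth" in f:
            tg = f["truth"]
            cohort.true_amplitudes = pd.DataFrame(
                {
                    **{
                        col: [s.decode() for s in tg[col][()]]
                        for col in (
                            "subject_id",
                            "group",
                            "condition",
                            "band",
                            "region",
                        )
                    },
                    "amplitude": tg["amplitude"][()],
                }
            )
    return cohort


def save_epoch_sets(path: str | Path, epoch_sets: dict[tuple[str, str], EpochSet]) -> None:
    """Write broadband epoch sets, one group per subject x condition."""
    with h5py.File(path, "w") as f:
        for (sid, cond), es in epoch_sets.items():
            g = f.create_group(f"{sid}/{cond}")
            d = g.create_dataset("epochs", data=es.epochs)
            d.attrs["sampling_rate"] = es.sampling_rate
            d.attrs["epoch_length"] = es.epoch_length
            g.create_dataset("retained_indices", data=es.retained_indices)


def load_epoch_sets(path: str | Path) -> dict[tuple[str, str], EpochSet]:
    out: dict[tuple[str, str], EpochSet] = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            for cond in f[sid]:
                g = f[f"{sid}/{cond}"]
                d = g["epochs"]
                out[(sid, cond)] = EpochSet(
                    epochs=d[()],
                    sampling_rate=float(d.attrs["sampling_rate"]),
                    epoch_length=float(d.attrs["epoch_length"]),
                    retained_indices=g["retained_indices"][()],
                    subject_id=sid,
                    condition=cond,
                )
    return out


def write_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
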