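"""Readers and writers for trials and pipeline products.

Three on-disk forms are supported:

* an mvnx-style XML dialect restricted to the ``jointAngle`` and
  ``position`` frame payloads (all other mvnx content is ignored on read
  and never written).  Joint order is declared in ``<joints>``; each frame
  stores three angles per joint in the ZXY component order
  (abduction/adduction, internal/external rotation, flexion/extension) and
  x/y/z metres per declared segment, gravity-aligned, z up.  Optional
  ``<footContacts>`` rows carry left/right stance flags;
* a long-format CSV (``time_s, joint, side, dof, value_deg``) with sibling
  ``*_positions.csv`` (``time_s, point, x_m, y_m, z_m``) and optional
  ``*_events.csv`` (``time_s, left_contact, right_contact``) files;
* a self-describing ``.npz`` archive for normalized-curve ensembles.

Loaders never reorder, resample or impute: sample count and sample rate
are preserved exactly, and NaNs are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .channels import (
    ANGLE_CHANNELS,
    MVNX_DOF_ORDER,
    MVNX_JOINT_LABELS,
    JOINT_SIDE_TO_MVNX,
    MVNX_POSITION_SEGMENTS,
    POSITION_POINTS,
    ChannelKey,
    Dof,
    Joint,
    Side,
)
from .normalize import NormalizedEnsemble
from .recording import Recording

_FMT = "%.17g"  # lossless float round trip in text


def _fmt(values: np.ndarray) -> str:
    return " ".join(_FMT % v for v in np.asarray(values).ravel())


def _parse_floats(texts: list[str]) -> np.ndarray:
    return np.array(" ".join(texts).split(), dtype=float)


# --------------------------------------------------------------------------
# mvnx
# --------------------------------------------------------------------------

_SEGMENT_TO_POINT = dict(MVNX_POSITION_SEGMENTS)
_POINT_TO_SEGMENT = {v: k for k, v in MVNX_POSITION_SEGMENTS.items()}


def write_mvnx(rec: Recording, path: str | Path) -> Path:
    """Write a recording in the mvnx dialect described above."""
    rec.require_full_channel_set()
    path = Path(path)
    joints = [JOINT_SIDE_TO_MVNX[(j, s)] for j, s in dict.fromkeys((k.joint, k.side) for k in ANGLE_CHANNELS)]
    segments = [_POINT_TO_SEGMENT[p] for p in POSITION_POINTS if p in rec.positions]

    root = etree.Element("mvnx", version="gaitspm-1")
    subj = etree.SubElement(
        root, "subject",
        label=rec.trial_id, condition=rec.condition, frameRate=_FMT % rec.sample_rate,
    )
    joints_el = etree.SubElement(subj, "joints")
    for label in joints:
        etree.SubElement(joints_el, "joint", label=label)
    seg_el = etree.SubElement(subj, "segments")
    for label in segments:
        etree.SubElement(seg_el, "segment", label=label)

    T = rec.n_samples
    angle_mat = np.empty((T, len(joints) * 3))
    for ji, label in enumerate(joints):
        joint, side = MVNX_JOINT_LABELS[label]
        for di, dof in enumerate(MVNX_DOF_ORDER):
            angle_mat[:, 3 * ji + di] = rec.angles[ChannelKey(joint, side, dof)]
    pos_mat = (
        np.concatenate([rec.positions[_SEGMENT_TO_POINT[s]] for s in segments], axis=1)
        if segments else None
    )

    frames = etree.SubElement(subj, "frames", count=str(T))
    for i in range(T):
        fr = etree.SubElement(frames, "frame", index=str(i), time=_FMT % (i / rec.sample_rate))
        etree.SubElement(fr, "jointAngle").text = _fmt(angle_mat[i])
        if pos_mat is not None:
            etree.SubElement(fr, "position").text = _fmt(pos_mat[i])
        if rec.event_flags is not None:
            l = int(rec.event_flags[Side.LEFT][i])
            r = int(rec.event_flags[Side.RIGHT][i])
            etree.SubElement(fr, "footContacts").text = f"{l} {r}"
    etree.ElementTree(root).write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
    return path


def read_mvnx(path: str | Path) -> Recording:
    """Read a recording from the mvnx dialect.

    Raises :class:`lxml.etree.XMLSyntaxError` for malformed XML and
    :class:`ValueError` naming the channel when a required joint label is
    missing.
    """
    tree = etree.parse(str(path))  # XMLSyntaxError propagates
    subj = tree.find("subject")
    if subj is None:
        raise ValueError(f"{path}: no <subject> element")
    sample_rate = float(subj.get("frameRate", "240"))
    condition = subj.get("condition", "WR")
    trial_id = subj.get("label", Path(path).stem)

    joint_labels = [j.get("label") for j in subj.findall("joints/joint")]
    unknown = [l for l in joint_labels if l not in MVNX_JOINT_LABELS]
    if unknown:
        raise ValueError(f"{path}: unknown joint label(s) {unknown}; the reader targets a fixed schema subset")
    present = {MVNX_JOINT_LABELS[l] for l in joint_labels}
    required = dict.fromkeys((k.joint, k.side) for k in ANGLE_CHANNELS)
    missing = [f"{j.value}/{s.value}" if s is not Side.NONE else j.value
               for j, s in required if (j, s) not in present]
    if missing:
        raise ValueError(f"{path}: missing required joint channel(s): {', '.join(missing)}")

    seg_labels = [s.get("label") for s in subj.findall("segments/segment")]
    bad_seg = [l for l in seg_labels if l not in _SEGMENT_TO_POINT]
    if bad_seg:
        raise ValueError(f"{path}: unknown position segment(s) {bad_seg}")

    frames = subj.findall("frames/frame")
    if not frames:
        raise ValueError(f"{path}: no frames")
    T = len(frames)

    angle_rows = [fr.findtext("jointAngle") for fr in frames]
    if any(r is None for r in angle_rows):
        raise ValueError(f"{path}: frame without jointAngle payload")
    angle_mat = _parse_floats(angle_rows).reshape(T, len(joint_labels) * 3)

    angles: dict[ChannelKey, np.ndarray] = {}
    for ji, label in enumerate(joint_labels):
        joint, side = MVNX_JOINT_LABELS[label]
        for di, dof in enumerate(MVNX_DOF_ORDER):
            angles[ChannelKey(joint, side, dof)] = angle_mat[:, 3 * ji + di].copy()

    positions: dict[str, np.ndarray] = {}
    if seg_labels:
        pos_rows = [fr.findtext("position") for fr in frames]
        if any(r is None for r in pos_rows):
            raise ValueError(f"{path}: frame without position payload despite declared segments")
        pos_mat = _parse_floats(pos_rows).reshape(T, len(seg_labels) * 3)
        for si, label in enumerate(seg_labels):
            positions[_SEGMENT_TO_POINT[label]] = pos_mat[:, 3 * si: 3 * si + 3].copy()

    flags = None
    fc = [fr.findtext("footContacts") for fr in frames]
    if all(f is not None for f in fc):
        mat = _parse_floats(fc).reshape(T, 2).astype(bool)
        flags = {Side.LEFT: mat[:, 0], Side.RIGHT: mat[:, 1]}

    return Recording(
        trial_id=trial_id, condition=condition, sample_rate=sample_rate,
        angles=angles, positions=positions, event_flags=flags,
    )


# --------------------------------------------------------------------------
# long-format CSV
# --------------------------------------------------------------------------


def _sibling(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix)


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    """Write a recording as long-format CSV files.

    ``path`` receives the angle rows; positions and (if present) contact
    flags go to sibling ``*_positions.csv`` / ``*_events.csv`` files.  A
    comment header carries trial metadata.
    """
    path = Path(path)
    header = f"# trial_id={rec.trial_id} condition={rec.condition} sample_rate={_FMT % rec.sample_rate}\n"
    times = rec.times()
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("time_s,joint,side,dof,value_deg\n")
        for i, ti in enumerate(times):
            ts = _FMT % ti
            for key in ANGLE_CHANNELS:
                if key in rec.angles:
                    fh.write(f"{ts},{key.joint.value},{key.side.value},{key.dof.value},{_FMT % rec.angles[key][i]}\n")
    if rec.positions:
        with open(_sibling(path, "_positions.csv"), "w") as fh:
            fh.write(header)
            fh.write("time_s,point,x_m,y_m,z_m\n")
            for i, ti in enumerate(times):
                ts = _FMT % ti
                for point in POSITION_POINTS:
                    if point in rec.positions:
                        x, y, z = rec.positions[point][i]
                        fh.write(f"{ts},{point},{_FMT % x},{_FMT % y},{_FMT % z}\n")
    if rec.event_flags is not None:
        with open(_sibling(path, "_events.csv"), "w") as fh:
            fh.write(header)
            fh.write("time_s,left_contact,right_contact\n")
            for i, ti in enumerate(times):
                fh.write(f"{_FMT % ti},{int(rec.event_flags[Side.LEFT][i])},{int(rec.event_flags[Side.RIGHT][i])}\n")
    return path


def _read_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
    return meta


def read_angles_csv(path: str | Path, positions_path: str | Path | None = None) -> Recording:
    """Read a long-format angle CSV (plus sibling positions/events files).

    Rows must appear in non-decreasing time order; duplicate
    (time, channel) rows and non-monotone time are rejected.
    """
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#", dtype={"side": str}, float_precision="round_trip")
    required_cols = {"time_s", "joint", "side", "dof", "value_deg"}
    if not required_cols.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required_cols)}")
    times = df["time_s"].to_numpy()
    if np.any(np.diff(times) < 0):
        raise ValueError(f"{path}: non-monotone time column")
    if df.duplicated(subset=["time_s", "joint", "side", "dof"]).any():
        raise ValueError(f"{path}: duplicate (time, channel) rows")
    if df["value_deg"].isna().any():
        raise ValueError(f"{path}: NaN angle values")

    unique_times = np.unique(times)
    sample_rate = float(meta.get("sample_rate", "nan"))
    if not np.isfinite(sample_rate):
        if unique_times.size < 2:
            raise ValueError(f"{path}: cannot infer sample rate from a single time point")
        sample_rate = 1.0 / float(np.median(np.diff(unique_times)))

    angles: dict[ChannelKey, np.ndarray] = {}
    for (joint, side, dof), group in df.groupby(["joint", "side", "dof"], sort=False):
        key = ChannelKey(Joint(joint), Side(side), Dof(dof))
        if len(group) != unique_times.size:
            raise ValueError(f"{path}: channel {key.label} has {len(group)} rows, expected {unique_times.size}")
        angles[key] = group["value_deg"].to_numpy(dtype=float)

    positions: dict[str, np.ndarray] = {}
    ppath = Path(positions_path) if positions_path else _sibling(path, "_positions.csv")
    if ppath.exists():
        pdf = pd.read_csv(ppath, comment="#", float_precision="round_trip")
        for point, group in pdf.groupby("point", sort=False):
            if point not in POSITION_POINTS:
                raise ValueError(f"{ppath}: unknown position point {point!r}")
            positions[point] = group[["x_m", "y_m", "z_m"]].to_numpy(dtype=float)

    flags = None
    epath = _sibling(path, "_events.csv")
    if epath.exists():
        edf = pd.read_csv(epath, comment="#")
        flags = {
            Side.LEFT: edf["left_contact"].to_numpy(dtype=bool),
            Side.RIGHT: edf["right_contact"].to_numpy(dtype=bool),
        }

    return Recording(
        trial_id=meta.get("trial_id", path.stem),
        condition=meta.get("condition", "WR"),
        sample_rate=sample_rate,
        angles=angles,
        positions=positions,
        event_flags=flags,
    )


# --------------------------------------------------------------------------
# Ensemble archive
# --------------------------------------------------------------------------


def write_ensemble(ens: NormalizedEnsemble, path: str | Path) -> Path:
    """Persist an ensemble as a self-describing .npz archive."""
    path = Path(path)
    meta = {
        "subjects": ens.subjects,
        "conditions": list(ens.conditions),
        "fields": [[j.value, d.value, p] for j, d, p in ens.fields],
        "n_nodes": ens.n_nodes,
    }
    np.savez(path, steps=ens.steps, median=ens.median, iqr=ens.iqr, meta=json.dumps(meta))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_ensemble(path: str | Path) -> NormalizedEnsemble:
    """Load an ensemble archive, validating shape against its metadata.

    The node count is taken from the archive as stored — never resampled.
    """
    with np.load(str(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        steps, median, iqr = z["steps"], z["median"], z["iqr"]
    fields = [(Joint(j), Dof(d), p) for j, d, p in meta["fields"]]
    expected = (len(meta["subjects"]), len(meta["conditions"]), len(fields), steps.shape[3], meta["n_nodes"])
    if steps.shape != expected:
        raise ValueError(f"{path}: stored shape {steps.shape} does not match metadata {expected}")
    return NormalizedEnsemble(
        steps=steps, median=median, iqr=iqr,
        subjects=list(meta["subjects"]), fields=fields,
        conditions=tuple(meta["conditions"]), n_nodes=int(meta["n_nodes"]),
    )
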