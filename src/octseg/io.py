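"""Dataset and checkpoint I/O.

Datasets live under a root directory: 8-bit grayscale PNG B-scans,
per-volume boundary CSVs (columns: scan_id, column, ilm_row, rpe_row)
and a JSON manifest recording participants, groups, geometry, config
and the generator seed.  Checkpoints are NumPy ``.npz`` archives of the
network state with a JSON sidecar recording the architecture config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .phantom import (BoundarySet, BScan, CohortManifest, Participant,
                      PhantomConfig, VolumeRecord)
from .segnet import NetConfig, build_network


def write_png(pixels: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="L").save(path)


def read_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.uint8)


def boundaries_frame(boundaries: list, scan_ids: list) -> pd.DataFrame:
    """Stack per-scan BoundarySets into the CSV dialect."""
    frames = []
    for sid, b in zip(scan_ids, boundaries):
        frames.append(pd.DataFrame({
            "scan_id": sid,
            "column": np.arange(b.width),
            "ilm_row": b.ilm_rows,
            "rpe_row": b.rpe_rows,
        }))
    return pd.concat(frames, ignore_index=True)


def frame_to_boundaries(df: pd.DataFrame) -> dict:
    """Inverse of :func:`boundaries_frame`: scan_id -> BoundarySet."""
    out = {}
    for sid, g in df.groupby("scan_id", sort=False):
        g = g.sort_values("column")
        out[sid] = BoundarySet(g["ilm_row"].to_numpy(),
                               g["rpe_row"].to_numpy())
    return out


def _scan_id(pid: str, visit: int, scan_index: int) -> str:
    return f"{pid}_v{visit}_s{scan_index:03d}"


def write_dataset(manifest: CohortManifest, root) -> Path:
    """Write PNGs + boundary CSVs + manifest.json under ``root``.

    Deterministic for a fixed manifest (no timestamps), so re-simulation
    with the same seed is byte-reproducible.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    mani = {
        "seed": manifest.seed,
        "config": dataclasses.asdict(manifest.config),
        "participants": [],
    }
    for p in manifest.participants:
        pentry = {
            "participant_id": p.participant_id,
            "group": p.group,
            "atrophy_severity": p.atrophy_severity,
            "baseline_volume_mm3": p.baseline_volume_mm3,
            "volumes": [],
        }
        for vol in p.volumes:
            vdir = root / p.participant_id / f"v{vol.visit}"
            vdir.mkdir(parents=True, exist_ok=True)
            scan_ids = []
            ventry = {"visit": vol.visit, "scans": [],
                      "boundaries": str((vdir / "boundaries.csv")
                                        .relative_to(root))}
            for scan, bnd in zip(vol.bscans, vol.boundaries):
                sid = _scan_id(p.participant_id, vol.visit, scan.scan_index)
                img_rel = str((vdir / f"{sid}.png").relative_to(root))
                write_png(scan.pixels, root / img_rel)
                ventry["scans"].append({
                    "scan_id": sid, "scan_index": scan.scan_index,
                    "image": img_rel, "eye": scan.eye,
                    "valid_start": bnd.valid_start,
                    "valid_end": bnd.valid_end,
                })
                scan_ids.append(sid)
            boundaries_frame(vol.boundaries, scan_ids).to_csv(
                vdir / "boundaries.csv", index=False)
            pentry["volumes"].append(ventry)
        mani["participants"].append(pentry)
    (root / "manifest.json").write_text(json.dumps(mani, indent=1,
                                                   sort_keys=True))
    return root


def read_dataset(root) -> CohortManifest:
    root = Path(root)
    mani = json.loads((root / "manifest.json").read_text())
    config = PhantomConfig(**mani["config"])
    participants = []
    for pe in mani["participants"]:
        p = Participant(participant_id=pe["participant_id"], group=pe["group"],
                        atrophy_severity=pe["atrophy_severity"],
                        baseline_volume_mm3=pe["baseline_volume_mm3"])
        for ve in pe["volumes"]:
            vol = VolumeRecord(participant_id=p.participant_id,
                               visit=ve["visit"])
            bnds = frame_to_boundaries(pd.read_csv(root / ve["boundaries"]))
            for se in ve["scans"]:
                if not (root / se["image"]).exists():
                    raise FileNotFoundError(f"missing scan image {se['image']}")
                px = read_png(root / se["image"])
                vol.bscans.append(BScan(
                    px, lateral_res_um=config.lateral_res_um,
                    axial_res_um=config.axial_res_um,
                    scan_spacing_um=config.scan_spacing_um,
                    participant_id=p.participant_id, eye=se.get("eye", "OD"),
                    visit=ve["visit"], scan_index=se["scan_index"]))
                b = bnds[se["scan_id"]]
                b.valid_start = se.get("valid_start", 0)
                b.valid_end = se.get("valid_end", b.width - 1)
                vol.boundaries.append(b)
            p.volumes.append(vol)
        participants.append(p)
    return CohortManifest(participants=participants, config=config,
                          seed=mani["seed"])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(net, path) -> None:
    """Network state as .npz with a JSON sidecar holding the NetConfig."""
    path = Path(path)
    arrays = {f"a{i}": a for i, a in enumerate(net.state_arrays())}
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"net_config": net.cfg.to_dict()}, indent=1))


def load_checkpoint(path):
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    net = build_network(NetConfig.from_dict(meta["net_config"]))
    data = np.load(path)
    net.set_state([data[f"a{i}"] for i in range(len(data.files))])
    return net
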