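"""Plain-text I/O: TSV tables, GMT gene sets, flat key=value configs.

Column conventions
------------------
tracks      : track_id, frame, t_s, x_um, y_um
counts      : gene_id, length_bp, then one column per sample
spike       : sample_id, spike_reads  (sidecar for counts)
trajectory  : t_h, V_fL, then optional content columns (protein, RNA, ...)
smr         : cell_id, mb1_pg, mb2_pg, rhof1, rhof2
induction   : cell_id, t_min, raw, field_bg
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .gems import Track
from .growth import GrowthTrajectory
from .induction import InductionTrace
from .rnaseq import CountMatrix
from .smr import BuoyantPair

__all__ = [
    "read_tracks_tsv",
    "write_tracks_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_trajectory_tsv",
    "write_trajectory_tsv",
    "read_buoyant_pairs_tsv",
    "write_buoyant_pairs_tsv",
    "read_induction_tsv",
    "write_induction_tsv",
    "read_gmt",
    "write_gmt",
    "read_flat_config",
]


def read_tracks_tsv(path) -> list[Track]:
    df = pd.read_csv(path, sep="\t")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                id=str(tid),
                t=grp["t_s"].to_numpy(),
                x=grp["x_um"].to_numpy(),
                y=grp["y_um"].to_numpy(),
            )
        )
    return tracks


def write_tracks_tsv(tracks: list[Track], path) -> None:
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": tr.id,
                    "frame": np.arange(tr.n_frames),
                    "t_s": tr.t,
                    "x_um": tr.x,
                    "y_um": tr.y,
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path, spike_path, volumes_path=None) -> CountMatrix:
    """Read a counts TSV and its spike-reads sidecar (and optional volumes)."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    lengths = df.pop("length_bp")
    spike = pd.read_csv(spike_path, sep="\t", index_col="sample_id")[
        "spike_reads"
    ]
    spike = spike.reindex(df.columns)
    volumes = None
    if volumes_path is not None:
        volumes = pd.read_csv(volumes_path, sep="\t", index_col="sample_id")[
            "volume_fL"
        ].reindex(df.columns)
    return CountMatrix(
        counts=df, lengths=lengths, spike_reads=spike, volumes=volumes
    )


def write_counts_tsv(cm: CountMatrix, path, spike_path, volumes_path=None):
    out = cm.counts.copy()
    out.insert(0, "length_bp", cm.lengths)
    out.to_csv(path, sep="\t", index_label="gene_id")
    cm.spike_reads.rename("spike_reads").to_csv(
        spike_path, sep="\t", index_label="sample_id"
    )
    if volumes_path is not None and cm.volumes is not None:
        cm.volumes.rename("volume_fL").to_csv(
            volumes_path, sep="\t", index_label="sample_id"
        )


def read_trajectory_tsv(path) -> GrowthTrajectory:
    df = pd.read_csv(path, sep="\t")
    content_cols = [c for c in df.columns if c not in ("t_h", "V_fL", "vacuole_fL")]
    return GrowthTrajectory(
        t=df["t_h"].to_numpy(),
        V=df["V_fL"].to_numpy(),
        content={c: df[c].to_numpy() for c in content_cols},
        vacuole=df["vacuole_fL"].to_numpy() if "vacuole_fL" in df else None,
    )


def write_trajectory_tsv(traj: GrowthTrajectory, path) -> None:
    df = pd.DataFrame({"t_h": traj.t, "V_fL": traj.V})
    for name, vals in traj.content.items():
        df[name] = vals
    if traj.vacuole is not None:
        df["vacuole_fL"] = traj.vacuole
    df.to_csv(path, sep="\t", index=False)


def read_buoyant_pairs_tsv(path) -> list[BuoyantPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        BuoyantPair(
            m_b1=r.mb1_pg, m_b2=r.mb2_pg, rho_f1=r.rhof1, rho_f2=r.rhof2
        )
        for r in df.itertuples()
    ]


def write_buoyant_pairs_tsv(pairs: list[BuoyantPair], path) -> None:
    pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(len(pairs))],
            "mb1_pg": [p.m_b1 for p in pairs],
            "mb2_pg": [p.m_b2 for p in pairs],
            "rhof1": [p.rho_f1 for p in pairs],
            "rhof2": [p.rho_f2 for p in pairs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_induction_tsv(path) -> list[InductionTrace]:
    df = pd.read_csv(path, sep="\t")
    traces = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_min")
        traces.append(
            InductionTrace(
                cell_id=str(cid),
                t=grp["t_min"].to_numpy(),
                raw=grp["raw"].to_numpy(),
                field_background=grp["field_bg"].to_numpy(),
            )
        )
    return traces


def write_induction_tsv(traces: list[InductionTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "t_min": tr.t,
                "raw": tr.raw,
                "field_bg": tr.field_background,
            }
        )
        for tr in traces
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, frozenset]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> ...."""
    sets: dict[str, frozenset] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if not genes:
            raise ValueError(f"empty gene set {name!r}")
        sets[name] = frozenset(genes)
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_flat_config(path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file (# comments allowed)."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = val
    return out
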