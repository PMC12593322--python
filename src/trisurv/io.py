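"""Delimited-text file formats for records, scores, meshes and results.

Everything is plain text so that a run manifest (seeds + configuration)
reproduces every number in a report.  Floats are written with full
precision ('%.17g') so write-then-read is the identity.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .survival import SurvivalData
from .triangulation import Triangulation


def write_records(data: SurvivalData, path) -> None:
    """Survival records as CSV: id, L, R (inf allowed), Z columns."""
    df = pd.DataFrame({"id": np.arange(len(data)), "L": data.L, "R": data.R})
    for j in range(data.Z.shape[1]):
        df[f"Z{j + 1}"] = data.Z[:, j]
    df.to_csv(path, index=False, float_format="%.17g")


def read_records(path, xi=None) -> SurvivalData:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("L", "R"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    zcols = sorted((c for c in df.columns if c.startswith("Z")),
                   key=lambda c: int(c[1:]))
    return SurvivalData(df["L"].to_numpy(dtype=float),
                        df["R"].to_numpy(dtype=float),
                        df[zcols].to_numpy(dtype=float), xi=xi)


def write_scores(xi: np.ndarray, path, center=None, scale=None) -> None:
    """Score matrix as CSV (subject, xi1..xiq) plus an optional sidecar JSON
    with the standardization parameters."""
    df = pd.DataFrame(xi, columns=[f"xi{j + 1}" for j in range(xi.shape[1])])
    df.insert(0, "id", np.arange(len(df)))
    df.to_csv(path, index=False, float_format="%.17g")
    if center is not None:
        side = {"center": np.asarray(center).tolist(),
                "scale": np.asarray(scale).tolist()}
        with open(str(path) + ".json", "w") as f:
            json.dump(side, f)


def read_scores(path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = sorted((c for c in df.columns if c.startswith("xi")),
                  key=lambda c: int(c[2:]))
    return df[cols].to_numpy(dtype=float)


def write_images(images: np.ndarray, points: np.ndarray, path) -> None:
    """Long-format image samples: subject, s1, s2, Y."""
    n, npts = images.shape
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n), npts),
        "s1": np.tile(points[:, 0], n),
        "s2": np.tile(points[:, 1], n),
        "Y": images.ravel(),
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_images(path):
    df = pd.read_csv(path, float_precision="round_trip")
    subjects = np.unique(df["subject"])
    first = df[df["subject"] == subjects[0]]
    points = first[["s1", "s2"]].to_numpy(dtype=float)
    images = df["Y"].to_numpy(dtype=float).reshape(len(subjects), len(points))
    return images, points


def write_mesh(mesh: Triangulation, path) -> None:
    mesh.to_file(path)


def read_mesh(path) -> Triangulation:
    return Triangulation.from_file(path)


def write_fit_report(result, path) -> None:
    """Machine-readable fit summary keyed by (rho, lambda)."""
    payload = {
        "rho": result.params.rho,
        "lambda": result.lam,
        "converged": bool(result.converged),
        "n_iter": int(result.n_iter),
        "loglik": result.loglik,
        "penalized_loglik": result.penalized_loglik,
        "df": int(result.df),
        "aic": result.aic,
        "selected_triangles": [int(l) for l in result.selected],
        "omega": result.params.omega.tolist(),
        "beta": result.params.beta.tolist(),
        "gamma": None if result.params.gamma is None else result.params.gamma.tolist(),
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)
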