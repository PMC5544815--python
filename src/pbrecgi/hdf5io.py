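"""HDF5 container for run artifacts.

Layout of one run file:

    /geometry/heart/{vertices,faces}
    /geometry/torso/{vertices,faces}
    /geometry/electrodes
    /transfer/A
    /heart/potentials            (attr dt_ms)
    /body/potentials             (attr dt_ms)
    /sim/beats/<i>/phi_H         (attrs origin, model, dt_ms)
    /basis/{U_k,singular_values,component_range}
    /inverse/<method>/{phi_H_hat,lambda_t}   (+ /inverse/pbr/beta_t)
    /timing/<method>/{tau_act,tau_rec}

Region labels travel as CSV (vertex, label) next to the container.
"""

from __future__ import annotations

import csv

import h5py
import numpy as np

from .basis import SpatialBasis
from .geometry import TorsoHeartGeometry
from .inverse import PBRSolution, TikhonovSolution
from .mesh import TriSurfaceMesh
from .postprocessing import TimingMap
from .propagation import RegionLabels, SimulatedBeat
from .transfer import BodyPotentials, TransferMatrix


def save_geometry(f: h5py.File, geom: TorsoHeartGeometry) -> None:
    g = f.require_group("geometry")
    for name, mesh in (("heart", geom.heart), ("torso", geom.torso)):
        grp = g.require_group(name)
        grp.create_dataset("vertices", data=mesh.vertices)
        grp.create_dataset("faces", data=mesh.faces)
    g.create_dataset("electrodes", data=geom.electrodes)
    g.attrs["conductivity_S_per_m"] = geom.conductivity


def load_geometry(f: h5py.File) -> TorsoHeartGeometry:
    g = f["geometry"]
    heart = TriSurfaceMesh(g["heart/vertices"][()], g["heart/faces"][()])
    torso = TriSurfaceMesh(g["torso/vertices"][()], g["torso/faces"][()])
    return TorsoHeartGeometry(heart=heart, torso=torso,
                              electrodes=g["electrodes"][()],
                              conductivity=float(
                                  g.attrs.get("conductivity_S_per_m", 0.2)))


def save_transfer(f: h5py.File, T: TransferMatrix) -> None:
    g = f.require_group("transfer")
    g.create_dataset("A", data=T.A)
    if T.electrode_vertex_indices is not None:
        g.create_dataset("electrode_vertex_indices",
                         data=T.electrode_vertex_indices)


def load_transfer(f: h5py.File) -> TransferMatrix:
    g = f["transfer"]
    idx = (g["electrode_vertex_indices"][()]
           if "electrode_vertex_indices" in g else None)
    return TransferMatrix(A=g["A"][()], electrode_vertex_indices=idx)


def save_body_potentials(f: h5py.File, body: BodyPotentials) -> None:
    d = f.require_group("body").create_dataset("potentials", data=body.phi_B)
    d.attrs["dt_ms"] = body.dt


def load_body_potentials(f: h5py.File) -> BodyPotentials:
    d = f["body/potentials"]
    return BodyPotentials(phi_B=d[()], dt=float(d.attrs["dt_ms"]))


def save_heart_potentials(f: h5py.File, phi_H: np.ndarray,
                          dt: float = 1.0) -> None:
    d = f.require_group("heart").create_dataset("potentials", data=phi_H)
    d.attrs["dt_ms"] = dt


def save_beats(f: h5py.File, beats: list[SimulatedBeat]) -> None:
    g = f.require_group("sim/beats")
    for i, b in enumerate(beats):
        d = g.create_dataset(str(i), data=b.phi_H)
        d.attrs["origin"] = b.origin
        d.attrs["model"] = b.model
        d.attrs["dt_ms"] = b.dt


def load_beats(f: h5py.File) -> list[SimulatedBeat]:
    g = f["sim/beats"]
    out = []
    for i in sorted(g, key=int):
        d = g[i]
        out.append(SimulatedBeat(phi_H=d[()], origin=int(d.attrs["origin"]),
                                 model=str(d.attrs["model"]),
                                 dt=float(d.attrs["dt_ms"])))
    return out


def save_basis(f: h5py.File, basis: SpatialBasis) -> None:
    g = f.require_group("basis")
    g.create_dataset("U_k", data=basis.U_k)
    g.create_dataset("singular_values", data=basis.singular_values)
    g.create_dataset("component_range", data=np.asarray(basis.component_range))


def load_basis(f: h5py.File) -> SpatialBasis:
    g = f["basis"]
    lo, hi = (int(v) for v in g["component_range"][()])
    return SpatialBasis(U_k=g["U_k"][()],
                        singular_values=g["singular_values"][()],
                        component_range=(lo, hi))


def save_solution(f: h5py.File,
                  sol: TikhonovSolution | PBRSolution) -> None:
    g = f.require_group(f"inverse/{sol.method}")
    g.create_dataset("phi_H_hat", data=sol.phi_H_hat)
    g.create_dataset("lambda_t", data=sol.lambda_t)
    if isinstance(sol, PBRSolution):
        g.create_dataset("beta_t", data=sol.beta_t)


def save_timing(f: h5py.File, timing: TimingMap) -> None:
    g = f.require_group(f"timing/{timing.method}")
    g.create_dataset("tau_act", data=timing.tau_act)
    g.create_dataset("tau_rec", data=timing.tau_rec)
    if timing.fallback is not None:
        g.create_dataset("fallback", data=timing.fallback.astype(np.uint8))


def write_region_labels_csv(path: str, labels: RegionLabels) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex", "label"])
        for i, lab in enumerate(labels.labels):
            w.writerow([i, lab])


def read_region_labels_csv(path: str) -> RegionLabels:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))[1:]
    labels = np.empty(len(rows), dtype=object)
    for vertex, lab in rows:
        labels[int(vertex)] = lab
    return RegionLabels(labels.astype(str))


def write_timing_csv(path: str, timing: TimingMap) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex", "tau_act_ms", "tau_rec_ms", "method",
                    "fallback_flag"])
        fb = (timing.fallback if timing.fallback is not None
              else np.zeros(len(timing.tau_act), bool))
        for i in range(len(timing.tau_act)):
            w.writerow([i, timing.tau_act[i], timing.tau_rec[i],
                        timing.method, int(fb[i])])


def write_matrix_csv(path: str, mat: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(mat), delimiter=",")
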