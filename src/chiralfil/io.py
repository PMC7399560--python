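"""Filament conformations, ensembles, and file I/O.

A :class:`FilamentConformation` stores nucleotide-resolution geometry in
column arrays (positions, base vectors, base normals) together with the
(duplex_id, strand_id, bp_index) bookkeeping that the backbone and twist
analyses rely on.  Ensembles are ordered collections of conformations with
provenance, stored on disk in an HDF5 container (one group per
conformation) or exchanged with oxDNA-style topology/configuration text
files.

Lengths are nm internally; oxDNA files use simulation units and are
converted on read/write with the documented constant
:data:`chiralfil.constants.OXDNA_LENGTH_NM`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import h5py
import numpy as np

from .constants import OXDNA_LENGTH_NM

ENSEMBLE_FORMAT_VERSION = 1


class OxdnaParseError(ValueError):
    """Malformed oxDNA topology/configuration input."""


class EnsembleFormatError(ValueError):
    """Unreadable or version-incompatible internal ensemble file."""


class NucleotideSite(NamedTuple):
    """One nucleotide: position (nm), oxDNA base vector and base normal."""

    position: np.ndarray
    base_vector: np.ndarray
    normal_vector: np.ndarray
    strand_id: int
    duplex_id: int
    bp_index: int


@dataclass
class FilamentConformation:
    """Nucleotide-resolution snapshot of one filament.

    Parameters
    ----------
    positions, base_vectors, normal_vectors : (N, 3) float arrays in nm /
        unit vectors.
    strand_id : (N,) int array; 0 or 1 within each duplex.
    duplex_id : (N,) int array in ``0..n_duplex-1``.
    bp_index : (N,) int array; base-pair plane index along the duplex.
    """

    positions: np.ndarray
    base_vectors: np.ndarray
    normal_vectors: np.ndarray
    strand_id: np.ndarray
    duplex_id: np.ndarray
    bp_index: np.ndarray
    n_duplex: int = 6
    contour_length: float = 420.0
    diameter: float = 6.0
    design_label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.base_vectors = np.ascontiguousarray(self.base_vectors, dtype=float)
        self.normal_vectors = np.ascontiguousarray(self.normal_vectors,
                                                   dtype=float)
        self.strand_id = np.asarray(self.strand_id, dtype=np.int64)
        self.duplex_id = np.asarray(self.duplex_id, dtype=np.int64)
        self.bp_index = np.asarray(self.bp_index, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    def site(self, i: int) -> NucleotideSite:
        return NucleotideSite(self.positions[i], self.base_vectors[i],
                              self.normal_vectors[i], int(self.strand_id[i]),
                              int(self.duplex_id[i]), int(self.bp_index[i]))

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        n = self.n_sites
        for name in ("base_vectors", "normal_vectors"):
            v = getattr(self, name)
            norms = np.linalg.norm(v, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError(f"{name} are not unit vectors")
        triples = set(zip(self.duplex_id.tolist(), self.strand_id.tolist(),
                          self.bp_index.tolist()))
        if len(triples) != n:
            raise ValueError("(duplex_id, strand_id, bp_index) not unique")
        if self.contour_length <= 0 or self.diameter <= 0:
            raise ValueError("contour_length and diameter must be positive")
        for d in range(self.n_duplex):
            mask = self.duplex_id == d
            if not mask.any():
                raise ValueError(f"duplex {d} has no sites")
            s0 = np.count_nonzero(self.strand_id[mask] == 0)
            s1 = np.count_nonzero(self.strand_id[mask] == 1)
            if s0 != s1:
                raise ValueError(
                    f"duplex {d}: strand bp counts differ ({s0} vs {s1})")

    def bp_planes(self, duplex: int) -> np.ndarray:
        """Midpoint positions of one duplex at each bp plane, ordered."""
        mask = self.duplex_id == duplex
        bp = self.bp_index[mask]
        pos = self.positions[mask]
        strand = self.strand_id[mask]
        order = np.lexsort((strand, bp))
        bp, pos = bp[order], pos[order]
        uniq, inverse, counts = np.unique(bp, return_inverse=True,
                                          return_counts=True)
        if np.any(counts != 2):
            raise ValueError(f"duplex {duplex}: bp planes without exactly "
                             "two nucleotides")
        out = np.zeros((uniq.size, 3))
        np.add.at(out, inverse, pos)
        return out / 2.0

    def strand_positions(self, duplex: int, strand: int) -> np.ndarray:
        """Positions of one strand of one duplex, ordered by bp_index."""
        mask = (self.duplex_id == duplex) & (self.strand_id == strand)
        bp = self.bp_index[mask]
        pos = self.positions[mask]
        return pos[np.argsort(bp)]

    def mirrored(self) -> "FilamentConformation":
        """Mirror image (reflection through the yz plane, x -> -x)."""
        flip = np.array([-1.0, 1.0, 1.0])
        return FilamentConformation(
            self.positions * flip, self.base_vectors * flip,
            self.normal_vectors * flip, self.strand_id.copy(),
            self.duplex_id.copy(), self.bp_index.copy(), self.n_duplex,
            self.contour_length, self.diameter,
            self.design_label + "+mirror")


@dataclass
class ConformationEnsemble:
    """Ordered set of conformations plus provenance (sources or seed)."""

    conformations: list[FilamentConformation]
    provenance: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.conformations)

    def __iter__(self):
        return iter(self.conformations)

    def __getitem__(self, i):
        return self.conformations[i]

    def validate(self) -> None:
        if self.count < 1:
            raise ValueError("ensemble must contain at least one conformation")
        ref = self.conformations[0]
        for c in self.conformations:
            if (c.n_duplex != ref.n_duplex
                    or c.design_label != ref.design_label
                    or c.n_sites != ref.n_sites):
                raise ValueError("ensemble members are inhomogeneous")

    def mirrored(self) -> "ConformationEnsemble":
        prov = dict(self.provenance)
        prov["mirrored"] = True
        return ConformationEnsemble([c.mirrored() for c in self], prov)


# ---------------------------------------------------------------------------
# oxDNA text formats
# ---------------------------------------------------------------------------

def read_duplex_map(path) -> dict[int, tuple[int, int, int]]:
    """Read a tab-separated nucleotide -> (duplex, strand, bp) map.

    Expected header: nucleotide_id, duplex_id, strand_id, bp_index.
    """
    mapping = {}
    with open(path) as fh:
        header = fh.readline().split()
        expected = ["nucleotide_id", "duplex_id", "strand_id", "bp_index"]
        if header != expected:
            raise OxdnaParseError(
                f"duplex_map header {header!r} != {expected!r}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                nid, did, sid, bp = (int(x) for x in line.split())
            except ValueError as exc:
                raise OxdnaParseError(
                    f"duplex_map line {ln}: {line.strip()!r}") from exc
            mapping[nid] = (did, sid, bp)
    return mapping


def _pair_strands_from_topology(strand_of: np.ndarray) -> dict:
    """Default duplex assignment: consecutive strand pairs (0,1), (2,3), ...

    Strand ``2d`` is taken 5'->3' as bp_index 0..n-1 of duplex ``d``; its
    partner ``2d+1`` is complementary and antiparallel, so its nucleotides
    map to bp_index n-1..0.  Ambiguous topologies (odd strand count or
    length mismatch) must supply an explicit duplex_map.
    """
    strands = np.unique(strand_of)
    if strands.size % 2:
        raise OxdnaParseError(
            "odd number of strands: duplex pairing is ambiguous, supply a "
            "duplex_map")
    mapping = {}
    for d in range(strands.size // 2):
        ids_a = np.flatnonzero(strand_of == strands[2 * d])
        ids_b = np.flatnonzero(strand_of == strands[2 * d + 1])
        if ids_a.size != ids_b.size:
            raise OxdnaParseError(
                f"strands {strands[2*d]} and {strands[2*d+1]} have unequal "
                "lengths: supply a duplex_map")
        for bp, nid in enumerate(ids_a):
            mapping[int(nid)] = (d, 0, bp)
        for bp, nid in enumerate(ids_b[::-1]):
            mapping[int(nid)] = (d, 1, bp)
    return mapping


def read_oxdna(topology_path, configuration_path, duplex_map=None, *,
               n_duplex=None, contour_length=None, diameter=6.0,
               design_label="imported") -> ConformationEnsemble:
    """Read an oxDNA topology + (multi-frame) configuration pair.

    Positions and orientation vectors are converted from oxDNA simulation
    units to nm (1 unit = 0.8518 nm); velocities, if present, are ignored.
    """
    topology_path = Path(topology_path)
    configuration_path = Path(configuration_path)
    with open(topology_path) as fh:
        head = fh.readline().split()
        if len(head) < 2:
            raise OxdnaParseError(
                f"{topology_path.name} line 1: expected 'n_nucleotides "
                "n_strands'")
        n_nt, n_strands = int(head[0]), int(head[1])
        strand_of = np.zeros(n_nt, dtype=np.int64)
        for i in range(n_nt):
            parts = fh.readline().split()
            if len(parts) < 4:
                raise OxdnaParseError(
                    f"{topology_path.name} line {i + 2}: short nucleotide row")
            strand_of[i] = int(parts[0])
    if np.unique(strand_of).size != n_strands:
        raise OxdnaParseError(
            f"{topology_path.name}: header declares {n_strands} strands but "
            f"{np.unique(strand_of).size} appear")

    if duplex_map is not None:
        mapping = (duplex_map if isinstance(duplex_map, dict)
                   else read_duplex_map(duplex_map))
        missing = [i for i in range(n_nt) if i not in mapping]
        if missing:
            raise OxdnaParseError(
                f"duplex_map missing nucleotide ids (first: {missing[0]})")
    else:
        mapping = _pair_strands_from_topology(strand_of)

    duplex_id = np.array([mapping[i][0] for i in range(n_nt)])
    strand_id = np.array([mapping[i][1] for i in range(n_nt)])
    bp_index = np.array([mapping[i][2] for i in range(n_nt)])
    if n_duplex is None:
        n_duplex = int(duplex_id.max()) + 1

    conformations = []
    with open(configuration_path) as fh:
        ln = 0
        while True:
            header = fh.readline()
            ln += 1
            if not header:
                break
            if not header.strip():
                continue
            if not header.lstrip().startswith("t"):
                raise OxdnaParseError(
                    f"{configuration_path.name} line {ln}: expected "
                    f"'t = ...' header, got {header.strip()!r}")
            box_line = fh.readline(); ln += 1
            energy_line = fh.readline(); ln += 1
            if not box_line.lstrip().startswith("b") or \
                    not energy_line.lstrip().startswith("E"):
                raise OxdnaParseError(
                    f"{configuration_path.name} line {ln}: malformed frame "
                    "header (expected 'b = ...' then 'E = ...')")
            pos = np.zeros((n_nt, 3))
            a1 = np.zeros((n_nt, 3))
            a3 = np.zeros((n_nt, 3))
            for i in range(n_nt):
                row = fh.readline()
                ln += 1
                parts = row.split()
                if len(parts) < 9:
                    raise OxdnaParseError(
                        f"{configuration_path.name} line {ln}: frame "
                        f"{len(conformations)} truncated after {i} "
                        f"nucleotides (topology declares {n_nt})")
                vals = np.array(parts[:9], dtype=float)
                pos[i] = vals[:3]
                a1[i] = vals[3:6]
                a3[i] = vals[6:9]
            lc = contour_length
            if lc is None:
                lc = (bp_index.max() + 1) * 0.34
            conformations.append(FilamentConformation(
                pos * OXDNA_LENGTH_NM, a1, a3, strand_id, duplex_id,
                bp_index, n_duplex, lc, diameter, design_label))
    if not conformations:
        raise OxdnaParseError(
            f"{configuration_path.name}: no frames found")
    prov = {"source": "oxdna",
            "topology": str(topology_path),
            "configuration": str(configuration_path)}
    return ConformationEnsemble(conformations, prov)


def write_oxdna(ensemble: ConformationEnsemble, topology_path,
                configuration_path) -> None:
    """Write an ensemble as oxDNA topology + multi-frame configuration.

    The topology lists nucleotides grouped by (duplex, strand) so that the
    default pairing rule of :func:`read_oxdna` reconstructs the indexing.
    Bases are written as 'A' throughout (sequence handling is out of scope);
    velocities are written as zeros.
    """
    ref = ensemble[0]
    order = np.lexsort((ref.bp_index, ref.strand_id, ref.duplex_id))
    # strand 1 of each duplex must appear reversed (antiparallel convention)
    rows = []
    strand_counter = 0
    for d in range(ref.n_duplex):
        for s in (0, 1):
            idx = order[(ref.duplex_id[order] == d)
                        & (ref.strand_id[order] == s)]
            if s == 1:
                idx = idx[::-1]
            rows.append((strand_counter, idx))
            strand_counter += 1
    flat = np.concatenate([idx for _, idx in rows])
    with open(topology_path, "w") as fh:
        fh.write(f"{ref.n_sites} {strand_counter}\n")
        offset = 0
        for sid, idx in rows:
            n = idx.size
            for j in range(n):
                three = -1 if j == 0 else (offset + j - 1)
                five = -1 if j == n - 1 else (offset + j + 1)
                fh.write(f"{sid + 1} A {three} {five}\n")
            offset += n
    with open(configuration_path, "w") as fh:
        for t, conf in enumerate(ensemble):
            fh.write(f"t = {t}\n")
            fh.write("b = 1000 1000 1000\n")
            fh.write("E = 0 0 0\n")
            pos = conf.positions[flat] / OXDNA_LENGTH_NM
            a1 = conf.base_vectors[flat]
            a3 = conf.normal_vectors[flat]
            for p, b, n in zip(pos, a1, a3):
                fh.write(" ".join(f"{x:.12g}" for x in (*p, *b, *n))
                         + " 0 0 0 0 0 0\n")


# ---------------------------------------------------------------------------
# Internal HDF5 ensemble container
# ---------------------------------------------------------------------------

_FIELDS = ("positions", "base_vectors", "normal_vectors", "strand_id",
           "duplex_id", "bp_index")


def write_ensemble(ensemble: ConformationEnsemble, path) -> None:
    """Write the ensemble to the internal HDF5 container (lossless)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = ENSEMBLE_FORMAT_VERSION
        h5.attrs["count"] = ensemble.count
        h5.attrs["provenance"] = json.dumps(ensemble.provenance)
        for i, conf in enumerate(ensemble):
            g = h5.create_group(f"conf_{i:06d}")
            for name in _FIELDS:
                g.create_dataset(name, data=getattr(conf, name))
            g.attrs["n_duplex"] = conf.n_duplex
            g.attrs["contour_length"] = conf.contour_length
            g.attrs["diameter"] = conf.diameter
            g.attrs["design_label"] = conf.design_label


def read_ensemble(path) -> ConformationEnsemble:
    """Read an ensemble written by :func:`write_ensemble`."""
    try:
        h5 = h5py.File(path, "r")
    except OSError as exc:
        raise EnsembleFormatError(f"{path}: not an ensemble container "
                                  f"({exc})") from exc
    with h5:
        version = h5.attrs.get("format_version")
        if version != ENSEMBLE_FORMAT_VERSION:
            raise EnsembleFormatError(
                f"{path}: format version {version!r}, expected "
                f"{ENSEMBLE_FORMAT_VERSION}")
        provenance = json.loads(h5.attrs["provenance"])
        conformations = []
        for key in sorted(k for k in h5.keys() if k.startswith("conf_")):
            g = h5[key]
            conformations.append(FilamentConformation(
                *(np.asarray(g[name]) for name in _FIELDS),
                n_duplex=int(g.attrs["n_duplex"]),
                contour_length=float(g.attrs["contour_length"]),
                diameter=float(g.attrs["diameter"]),
                design_label=str(g.attrs["design_label"])))
    return ConformationEnsemble(conformations, provenance)
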