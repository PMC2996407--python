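"""Persistent label table: targets plus their reference sets, keyed by label.

Layout of the HDF5 container (documented so files are language-portable)::

    /                       attrs: schema_version, params (JSON), codec
    /targets/<tid>/ca       (N, 3) float64   Cα coordinates, Å
                   centroid (N, 3) float64   side-chain centroids, Å
                   depth    (N,)   float64   surface depths, Å
                   labels   (N,)   S1        one-letter residue labels
                   chain    (N,)   S4        author chain ids
                   seqnum   (N,)   int32     author residue numbers
                   icode    (N,)   S1        insertion codes
                   nbr_offsets/nbr_indices/nbr_distances  flattened 2r lists
                   attrs: label_counts (JSON), nbr_radius_2r
    /refsets/<KEY>/idx      (R, n) int32     residue-index n-tuples
                   block_targets (B,) str    per-block target ids
                   block_starts  (B+1,) int64  row partition of idx

KEY is the n sorted one-letter codes concatenated (e.g. "DHK").  Reference
sets for one key are stored as one matrix with a row-block index mapping row
ranges to targets, so a lookup touches only that key's datasets.  Lossless
gzip compression is enabled per dataset and declared in the file metadata.
"""

from __future__ import annotations

import json
import warnings

import h5py
import numpy as np

from .neighbors import DEFAULT_RADIUS, NeighborLists, precompute_neighbor_lists
from .refsets import GeometricParams, enumerate_reference_sets
from .structure_io import Residue, TargetStructure

__all__ = ["LabelTable", "build_table", "open_table"]

SCHEMA_VERSION = 1
_COMPRESSION = dict(compression="gzip", compression_opts=4)


def _ds(group, name, data, compress=False):
    # track_times=False keeps rebuilt tables byte-identical (reproducibility)
    kwargs = dict(_COMPRESSION) if compress else {}
    return group.create_dataset(name, data=data, track_times=False, **kwargs)


class TableError(RuntimeError):
    pass


class LabelTable:
    """Read handle over a built table file."""

    def __init__(self, path, mode="r"):
        self._f = h5py.File(path, mode)
        if "schema_version" not in self._f.attrs:
            raise TableError(f"{path}: not a label-table file (no schema header)")
        self.schema_version = int(self._f.attrs["schema_version"])
        self.params = GeometricParams.from_dict(json.loads(self._f.attrs["params"]))

    # -- context / lifecycle -------------------------------------------------
    def close(self):
        self._f.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- queries -------------------------------------------------------------
    @property
    def target_ids(self) -> list:
        return sorted(self._f["targets"].keys()) if "targets" in self._f else []

    def check_params(self, params: GeometricParams | None, override: bool = False):
        """Refuse queries whose geometric params differ from build time."""
        if params is None or override:
            return
        if params != self.params:
            raise TableError(
                "query params differ from the params this table was built with "
                f"({params.to_dict()} vs {self.params.to_dict()}); pass "
                "override_params=True only if you accept invalid statistics"
            )

    def lookup(self, key, target_filter=None) -> dict:
        """Map target_id -> list of residue-index n-tuples stored under key."""
        key = tuple(key)
        if list(key) != sorted(key):
            raise ValueError(f"lookup key must be sorted; got {key}")
        name = "".join(key)
        if "refsets" not in self._f or name not in self._f["refsets"]:
            return {}
        grp = self._f["refsets"][name]
        idx = grp["idx"][...]
        block_targets = [t.decode() for t in grp["block_targets"][...]]
        starts = grp["block_starts"][...]
        out = {}
        for b, tid in enumerate(block_targets):
            if target_filter is not None and tid not in target_filter:
                continue
            rows = idx[starts[b]:starts[b + 1]]
            if len(rows):
                out[tid] = [tuple(int(v) for v in row) for row in rows]
        return out

    def key_frequency(self, key, target_filter=None) -> int:
        """Total stored reference sets under key (within target_filter if given)."""
        key = tuple(key)
        if list(key) != sorted(key):
            raise ValueError(f"lookup key must be sorted; got {key}")
        name = "".join(key)
        if "refsets" not in self._f or name not in self._f["refsets"]:
            return 0
        grp = self._f["refsets"][name]
        if target_filter is None:
            return int(grp["idx"].shape[0])
        block_targets = [t.decode() for t in grp["block_targets"][...]]
        starts = grp["block_starts"][...]
        return int(
            sum(
                starts[b + 1] - starts[b]
                for b, tid in enumerate(block_targets)
                if tid in target_filter
            )
        )

    def keys(self) -> list:
        if "refsets" not in self._f:
            return []
        return [tuple(name) for name in sorted(self._f["refsets"].keys())]

    def label_counts(self, target_id) -> dict:
        """Stored residue-label counts of one target (attribute read only)."""
        if "targets" not in self._f or target_id not in self._f["targets"]:
            raise KeyError(f"target {target_id!r} not in table")
        return json.loads(self._f["targets"][target_id].attrs["label_counts"])

    def read_target(self, target_id) -> tuple:
        """Reconstruct a stored target and its neighbor lists."""
        if "targets" not in self._f or target_id not in self._f["targets"]:
            close = [t for t in self.target_ids if target_id.lower() in t.lower() or t.lower() in target_id.lower()]
            raise KeyError(
                f"target {target_id!r} not in table"
                + (f"; near misses: {close[:5]}" if close else "")
            )
        g = self._f["targets"][target_id]
        ca = g["ca"][...]
        centroid = g["centroid"][...]
        depth = g["depth"][...]
        labels = [b.decode() for b in g["labels"][...]]
        chain = [b.decode() for b in g["chain"][...]]
        seqnum = g["seqnum"][...]
        icode = [b.decode() for b in g["icode"][...]]
        residues = [
            Residue(
                chain_id=chain[i],
                seq_number=int(seqnum[i]),
                insertion_code=icode[i],
                label=labels[i],
                ca=ca[i],
                sidechain_centroid=centroid[i],
                depth=float(depth[i]),
            )
            for i in range(len(labels))
        ]
        target = TargetStructure(
            target_id=target_id,
            residues=residues,
            label_counts=json.loads(g.attrs["label_counts"]),
        )
        lists = NeighborLists.from_flat(
            g.attrs["nbr_radius_2r"],
            g["nbr_offsets"][...],
            g["nbr_indices"][...],
            g["nbr_distances"][...],
        )
        return target, lists


def build_table(
    targets,
    params: GeometricParams | None = None,
    path=None,
    neighbor_radius: float = DEFAULT_RADIUS,
) -> LabelTable:
    """Build a table file from parsed targets (one-shot; idempotent content).

    Per-target enumeration failures are logged as warnings and skipped;
    duplicate target ids abort the build.
    """
    params = params or GeometricParams()
    if path is None:
        raise TableError("build_table requires a writable path")
    by_key: dict = {}
    seen = set()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["params"] = json.dumps(params.to_dict(), sort_keys=True)
        f.attrs["codec"] = "gzip"
        tgrp = f.create_group("targets")
        for target in targets:
            if target.target_id in seen:
                raise TableError(f"duplicate target_id {target.target_id!r}")
            seen.add(target.target_id)
            try:
                refsets = enumerate_reference_sets(target, params)
                lists = precompute_neighbor_lists(target, neighbor_radius)
            except Exception as exc:  # per-target failure: log and skip
                warnings.warn(
                    f"skipping target {target.target_id}: {exc}", stacklevel=2
                )
                continue
            _write_target(tgrp, target, lists)
            for rs in refsets:
                by_key.setdefault(rs.key, {}).setdefault(target.target_id, []).append(
                    rs.residue_indices
                )
        rgrp = f.create_group("refsets")
        for key in sorted(by_key):
            per_target = by_key[key]
            tids = sorted(per_target)
            rows, starts = [], [0]
            for tid in tids:
                rows.extend(per_target[tid])
                starts.append(len(rows))
            g = rgrp.create_group("".join(key))
            _ds(g, "idx", np.array(rows, dtype=np.int32), compress=True)
            _ds(g, "block_targets", np.array(tids, dtype=h5py.string_dtype()))
            _ds(g, "block_starts", np.array(starts, dtype=np.int64))
    return LabelTable(path)


def _write_target(tgrp, target: TargetStructure, lists: NeighborLists):
    g = tgrp.create_group(target.target_id)
    n = len(target.residues)
    _ds(g, "ca", target.ca_coords, compress=n > 64)
    _ds(
        g,
        "centroid",
        np.array([r.sidechain_centroid for r in target.residues]).reshape(-1, 3),
        compress=n > 64,
    )
    _ds(g, "depth", target.depths)
    _ds(g, "labels", np.array([r.label.encode() for r in target.residues], dtype="S1"))
    _ds(g, "chain", np.array([r.chain_id.encode() for r in target.residues], dtype="S4"))
    _ds(g, "seqnum", np.array([r.seq_number for r in target.residues], dtype=np.int32))
    _ds(
        g,
        "icode",
        np.array([(r.insertion_code or "").encode() for r in target.residues], dtype="S1"),
    )
    offsets, cat_i, cat_d = lists.to_flat()
    _ds(g, "nbr_offsets", offsets)
    _ds(g, "nbr_indices", cat_i.astype(np.int32), compress=len(cat_i) > 64)
    _ds(g, "nbr_distances", cat_d, compress=len(cat_d) > 64)
    g.attrs["label_counts"] = json.dumps(target.label_counts, sort_keys=True)
    g.attrs["nbr_radius_2r"] = lists.radius_2r


def open_table(path) -> LabelTable:
    return LabelTable(path)
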