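"""Shared fixtures: hand-written PDB snippets and the seeded synthetic benchmark."""

import numpy as np
import pytest

from motifhash import (
    BenchmarkSpec,
    MatchOptions,
    match_motif,
    make_benchmark,
)

BENCHMARK_SEED = 2027


def pdb_atom(serial, name, resname, chain, resnum, xyz, occ=1.0, altloc=" ", icode=" ",
             element=None):
    element = element or name.strip()[0]
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {pad_name:<4s}{altloc}{resname} {chain}"
        f"{resnum:4d}{icode}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def make_pdb(residues):
    """Minimal PDB text from [(resname, chain, resnum, {atom: xyz}), ...]."""
    lines, serial = [], 1
    for resname, chain, resnum, atoms in residues:
        for name, xyz in atoms.items():
            lines.append(pdb_atom(serial, name, resname, chain, resnum, xyz))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_residue_pdb():
    """ALA, GLY, LYS on chain A, well separated."""
    return make_pdb(
        [
            ("ALA", "A", 1, {"N": (0, 1.4, 0), "CA": (0, 0, 0), "C": (1.4, 0, 0),
                             "CB": (-0.8, -1.2, 0.4)}),
            ("GLY", "A", 2, {"N": (3, 1.4, 0), "CA": (3.8, 0, 0), "C": (5.2, 0, 0)}),
            ("LYS", "A", 3, {"N": (7, 1.4, 0), "CA": (7.6, 0, 0), "C": (9.0, 0, 0),
                             "CB": (7.6, -1.5, 0.2), "CG": (8.2, -2.6, 1.0),
                             "CD": (8.0, -4.0, 0.6), "CE": (8.8, -5.0, 1.4),
                             "NZ": (8.6, -6.4, 1.0)}),
        ]
    )


class _Bench:
    def __init__(self, table, motif, truth, results):
        self.table = table
        self.motif = motif
        self.truth = truth
        self.results = results


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory):
    """The default synthetic benchmark: 200 targets, 50 % planted, σ = 0.25 Å.

    Built once per session; matching uses default options (ε = 7 Å, 15 seed
    reference sets, best complete match per target).
    """
    path = tmp_path_factory.mktemp("bench") / "bench.h5"
    spec = BenchmarkSpec(seed=BENCHMARK_SEED)
    # neighbor lists at 2x9 Å so both the default ε = 7 and the ε = 9
    # stability re-run can query the same table
    table, motif, truth = make_benchmark(spec, table_path=path, neighbor_radius=9.0)
    results = match_motif(motif, table, options=MatchOptions())
    bench = _Bench(table, motif, truth, results)
    bench.path = path
    bench.spec = spec
    yield bench
    table.close()


def kabsch_rmsd(P, Q):
    """Test-local SVD superposition oracle, independent of the package path."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return float(np.sqrt(((Pc @ R.T - Qc) ** 2).sum() / len(P)))
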