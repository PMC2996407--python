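"""Run configuration and the multi-process matching contract.

Targets are partitioned over worker processes; each worker opens the table
read-only and matches its share independently; the parent merges the
per-target results.  Because every target is handled by exactly one worker
and the output is sorted at serialization time, the aggregate is
bit-identical to a single-worker run for any worker count.
"""

from __future__ import annotations

import multiprocessing as mp
from dataclasses import asdict, dataclass, field

from .matcher import MatchOptions, MatchResults, match_motif
from .refsets import GeometricParams
from .table import LabelTable

__all__ = ["RunConfig", "run_parallel", "parse_config_file"]


@dataclass
class RunConfig:
    table_path: str = ""
    motif_spec_path: str = ""
    source_pdb_path: str = ""
    target_filter: list | None = None  # None = all targets
    params: GeometricParams = field(default_factory=GeometricParams)
    options: MatchOptions = field(default_factory=MatchOptions)
    workers: int = 1
    seed: int = 0  # fixtures only; matching itself is deterministic
    output_xml: str = "matches.xml"
    output_profile_tsv: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        return d


_CONFIG_FIELDS = {
    "epsilon": ("options", float),
    "candidate_radius": ("options", float),
    "max_seed_refsets": ("options", int),
    "keep_multiple_per_target": ("options", lambda s: s.lower() in ("1", "true", "yes")),
    "min_partial_size": ("options", int),
    "best_match_criterion": ("options", str),
    "n": ("params", int),
    "d_maxmindist": ("params", float),
    "d_diameter": ("params", float),
    "d_maxdepth": ("params", float),
    "d_maxmindepth": ("params", float),
    "check_depth": ("params", lambda s: s.lower() in ("1", "true", "yes")),
    "table_path": (None, str),
    "motif_spec_path": (None, str),
    "source_pdb_path": (None, str),
    "workers": (None, int),
    "seed": (None, int),
    "output_xml": (None, str),
    "output_profile_tsv": (None, str),
}


def parse_config_file(text: str) -> RunConfig:
    """Plain ``key = value`` config (one per line, # comments)."""
    opts: dict = {}
    par: dict = {}
    top: dict = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {ln}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in _CONFIG_FIELDS:
            raise ValueError(f"config line {ln}: unknown key {key!r}")
        where, conv = _CONFIG_FIELDS[key]
        parsed = conv(val)
        {None: top, "options": opts, "params": par}[where][key] = parsed
    return RunConfig(
        params=GeometricParams(**par),
        options=MatchOptions(**opts),
        **top,
    )


def _worker(args):
    table_path, motif, chunk, options, override, rank_filter = args
    with LabelTable(table_path) as table:
        res = match_motif(
            motif, table, target_filter=chunk, options=options,
            override_params=override, seed_rank_filter=rank_filter,
        )
    return res.per_target


def run_parallel(
    motif,
    table_path,
    target_filter=None,
    options: MatchOptions | None = None,
    workers: int = 1,
    override_params: bool = False,
) -> MatchResults:
    """Match a motif with ``workers`` processes; aggregation is order-free."""
    options = options or MatchOptions()
    with LabelTable(table_path) as table:
        params = table.params
        considered = (
            sorted(target_filter) if target_filter is not None else table.target_ids
        )
    if not considered:
        from .matcher import MatchResults as MR

        return MR(
            motif=motif, options=options, params=params, per_target={},
            targets_considered=[],
        )
    workers = max(1, min(workers, len(considered)))
    if workers == 1:
        with LabelTable(table_path) as table:
            return match_motif(
                motif, table, target_filter=considered, options=options,
                override_params=override_params,
            )
    chunks = [considered[i::workers] for i in range(workers)]
    jobs = [
        (str(table_path), motif, chunk, options, override_params, considered)
        for chunk in chunks
    ]
    ctx = mp.get_context("spawn")
    per_target: dict = {}
    with ctx.Pool(workers) as pool:
        try:
            for part in pool.map(_worker, jobs):
                per_target.update(part)
        except Exception as exc:
            raise RuntimeError(
                f"worker failure while matching batches {[c[:3] for c in chunks]}: {exc}"
            ) from exc
    return MatchResults(
        motif=motif,
        options=options,
        params=params,
        per_target=per_target,
        targets_considered=considered,
    )
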