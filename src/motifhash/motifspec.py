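"""Text format for motif definitions.

A motif spec names a source structure followed by whitespace- or
semicolon-separated residue tokens::

    spec        = source_id { sep token } ;
    token       = chain seq_number [ insertion ] WS labels ;
    chain       = letter ;  seq_number = integer ;  insertion = letter ;
    labels      = one or more one-letter amino-acid codes (allowed set) ;
    sep         = ";" | newline ;

Example: ``2MNR A164 KH; A195 D; A221 E; A247 EDN; A297 HK`` defines a
5-point motif whose first point sits at residue A164 of the source and may
match lysine or histidine.  Coordinates are pulled from the parsed source
structure; the residue's own label is implicitly allowed.
"""

from __future__ import annotations

import re

from .matcher import Motif, MotifPoint
from .structure_io import ALPHABET, TargetStructure

__all__ = ["parse_motif_spec", "format_motif_spec", "MotifSpecError"]

_TOKEN = re.compile(r"^([A-Za-z])(-?\d+)([A-Za-z]?)$")


class MotifSpecError(ValueError):
    pass


def parse_motif_spec(text: str, source_targets, min_points: int = 3) -> Motif:
    """Parse a motif spec against its parsed source structure(s).

    ``source_targets`` is one TargetStructure or a list covering the chains
    the spec references (e.g. the output of ``parse_structure``).  A motif
    must have at least ``min_points`` residues (the reference-set size n, by
    default 3) to be matchable at all.
    """
    if isinstance(source_targets, TargetStructure):
        source_targets = [source_targets]
    chunks = [c.strip() for c in re.split(r"[;\n]", text.strip()) if c.strip()]
    if not chunks:
        raise MotifSpecError("empty motif spec")
    head = chunks[0].split()
    if len(head) < 3 and len(chunks) == 1:
        raise MotifSpecError("motif spec must name a source id and residues")
    source_id = head[0]
    rest = [" ".join(head[1:])] + chunks[1:] if len(head) > 1 else chunks[1:]

    tokens = []
    for chunk in rest:
        parts = chunk.split()
        if len(parts) % 2 != 0:
            raise MotifSpecError(f"malformed motif token {chunk!r} (want 'A164 KH')")
        tokens.extend(zip(parts[0::2], parts[1::2]))
    if not tokens:
        raise MotifSpecError("motif spec contains no residues")

    points = []
    seen = set()
    for resid_txt, labels_txt in tokens:
        match = _TOKEN.match(resid_txt)
        if not match:
            raise MotifSpecError(f"cannot parse residue id {resid_txt!r}")
        chain, num, icode = match.group(1), int(match.group(2)), match.group(3)
        res_id = (chain, num, icode)
        if res_id in seen:
            raise MotifSpecError(f"duplicate residue id {resid_txt!r}")
        seen.add(res_id)
        labels = set(labels_txt.upper())
        bad = labels - ALPHABET
        if bad:
            raise MotifSpecError(
                f"label(s) {sorted(bad)} for {resid_txt!r} are not amino-acid codes"
            )
        residue = _find_residue(source_targets, res_id)
        if residue is None:
            raise MotifSpecError(
                f"residue {resid_txt!r} not found in source {source_id!r}"
            )
        labels.add(residue.label)
        points.append(
            MotifPoint(
                res_id=res_id,
                ca=tuple(residue.ca),
                allowed_labels=frozenset(labels),
                sidechain_centroid=tuple(residue.sidechain_centroid),
            )
        )
    if len(points) < min_points:
        raise MotifSpecError(
            f"motif has {len(points)} residue(s); at least {min_points} required "
            "(motif size m must reach the reference-set size n)"
        )
    return Motif(motif_id=source_id, source_structure=source_id, points=tuple(points))


def _find_residue(source_targets, res_id):
    for target in source_targets:
        for r in target.residues:
            if r.res_id == res_id:
                return r
    return None


def format_motif_spec(motif: Motif) -> str:
    """Serialize a motif back to spec text (round-trips with the parser)."""
    toks = []
    for p in motif.points:
        chain, num, icode = p.res_id
        toks.append(f"{chain}{num}{icode} {''.join(sorted(p.allowed_labels))}")
    return f"{motif.source_structure} " + "; ".join(toks)
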