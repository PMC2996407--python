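"""Deterministic XML output for match runs.

The document embeds full run provenance (config, table schema version, a
config hash) and one ``<match>`` element per reported match, sorted by
ascending p-value then target id so that identical inputs always produce
identical bytes regardless of worker count.  The schema ships in the repo
as ``schema/matches.xsd``.
"""

from __future__ import annotations

import hashlib
import json

from lxml import etree

from .significance import MotifProfile, corrected_pvalue

__all__ = ["matches_to_xml", "write_matches_xml", "read_matches_xml"]

XML_SCHEMA_VERSION = "1"


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def matches_to_xml(results, profile: MotifProfile | None = None, config: dict | None = None) -> bytes:
    """Serialize MatchResults (+ optional profile for p-values) to XML bytes."""
    config = dict(config or {})
    config.setdefault("match_options", _options_dict(results.options))
    config.setdefault("geometric_params", results.params.to_dict())
    cfg_json = json.dumps(config, sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]

    root = etree.Element("matchrun", version=XML_SCHEMA_VERSION)
    meta = etree.SubElement(root, "metadata")
    etree.SubElement(meta, "motif", id=results.motif.motif_id,
                     source=results.motif.source_structure,
                     size=str(results.motif.m))
    cfg_el = etree.SubElement(meta, "config", hash=cfg_hash)
    cfg_el.text = cfg_json
    etree.SubElement(
        meta, "targets", considered=str(len(results.targets_considered))
    )
    if profile is not None:
        etree.SubElement(
            meta,
            "profile",
            n_matched=str(profile.n_matched),
            n_missed=str(profile.n_missed),
            bandwidth=_fmt(profile.bandwidth),
            bandwidth_method=profile.bandwidth_method,
            w_match=_fmt(profile.w_match),
            epsilon=_fmt(profile.epsilon),
        )

    rows = []
    for match in results.matches:
        p = corrected_pvalue(profile, match.rmsd) if profile is not None else None
        rows.append((p if p is not None else 2.0, match.target_id, match, p))
    rows.sort(key=lambda r: (r[0], r[1], r[2].correspondence))

    body = etree.SubElement(root, "matches")
    for _, _, match, p in rows:
        attrs = {
            "target": match.target_id,
            "ca_rmsd": _fmt(match.rmsd),
            "size": str(match.size),
            "complete": "true" if match.complete else "false",
            "seed_key": "".join(match.seed_key),
        }
        if match.sidechain_centroid_rmsd is not None:
            attrs["centroid_rmsd"] = _fmt(match.sidechain_centroid_rmsd)
        if p is not None:
            attrs["p_value"] = f"{p:.6g}"
        el = etree.SubElement(body, "match", **attrs)
        for point_idx, (chain, num, icode) in match.correspondence:
            etree.SubElement(
                el,
                "pair",
                point=str(point_idx),
                chain=chain,
                seqnum=str(num),
                icode=icode,
            )
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _options_dict(options) -> dict:
    return {
        "epsilon": options.epsilon,
        "candidate_radius": options.radius,
        "max_seed_refsets": options.max_seed_refsets,
        "keep_multiple_per_target": options.keep_multiple_per_target,
        "min_partial_size": options.min_partial_size,
        "rmsd_weight": options.rmsd_weight,
        "best_match_criterion": options.best_match_criterion,
        "augmentation_order": options.augmentation_order,
    }


def write_matches_xml(results, profile, config, path) -> None:
    data = matches_to_xml(results, profile, config)
    with open(path, "wb") as fh:
        fh.write(data)


def read_matches_xml(path_or_bytes) -> list:
    """Parse a match XML back to a list of dicts (round-trip checking)."""
    if isinstance(path_or_bytes, bytes):
        root = etree.fromstring(path_or_bytes)
    else:
        root = etree.parse(str(path_or_bytes)).getroot()
    out = []
    for el in root.findall(".//match"):
        pairs = tuple(
            (
                int(p.get("point")),
                (p.get("chain"), int(p.get("seqnum")), p.get("icode")),
            )
            for p in el.findall("pair")
        )
        out.append(
            {
                "target_id": el.get("target"),
                "ca_rmsd": float(el.get("ca_rmsd")),
                "size": int(el.get("size")),
                "complete": el.get("complete") == "true",
                "seed_key": tuple(el.get("seed_key")),
                "centroid_rmsd": (
                    float(el.get("centroid_rmsd"))
                    if el.get("centroid_rmsd") is not None
                    else None
                ),
                "p_value": (
                    float(el.get("p_value")) if el.get("p_value") is not None else None
                ),
                "correspondence": pairs,
            }
        )
    return out
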