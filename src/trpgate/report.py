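"""Run-level report juxtaposing the four channel systems.

Combines whatever analyses are available per system (binding site, contact
occupancy, gate area, water crossings, RMSD replicates, binding fit,
statistical comparisons) into a single JSON-serialisable document plus a
human-readable markdown rendering.  Missing systems or sections are noted,
never fatal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .assays import BindingFit
from .contacts import ContactProfile
from .pore import GateGeometrySeries, PermeationEventLog
from .stats import GroupComparisonResult
from .superpose import ReplicateSummary

#: Canonical system labels in display order.
SYSTEM_ORDER = ("WT", "WT+EET", "K535A", "K535A+EET")


def _sig3(x):
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return x
    if x == 0:
        return 0.0
    return float(f"{x:.3g}")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _system_section(analyses: dict) -> dict:
    section: dict = {}
    site = analyses.get("binding_site")
    if site is not None:
        section["binding_site"] = [
            {"subunit": s, "residue": int(r)} for s, r in site
        ]
    prof = analyses.get("contact_profile")
    if isinstance(prof, ContactProfile):
        section["contact_occupancy"] = [
            {
                "subunit": r.subunit,
                "residue": int(r.residue_number),
                "resname": r.residue_name,
                "occupancy": float(r.occupancy),
                "mean_min_dist_A": float(r.mean_min_distance_A),
            }
            for r in prof.records
        ]
        section["contact_cutoff_A"] = prof.cutoff_A
    area = analyses.get("gate_area")
    if isinstance(area, GateGeometrySeries):
        section["gate_area"] = {
            "mean_A2": area.mean_A2,
            "sd_A2": area.sd_A2,
            "n_frames": int(area.area_A2.size),
            "segments": [
                {"label": lab, "mean_A2": m, "sd_A2": s}
                for lab, m, s in area.segment_summaries
            ],
        }
    elif isinstance(area, (tuple, list)) and len(area) == 2:
        section["gate_area"] = {"mean_A2": float(area[0]), "sd_A2": float(area[1])}
    log = analyses.get("crossings")
    if isinstance(log, PermeationEventLog):
        section["water_crossings"] = {
            "up": log.n_up,
            "down": log.n_down,
            "plane_offset_A": log.plane_offset_A,
        }
    elif isinstance(log, dict):
        section["water_crossings"] = dict(log)
    rmsd = analyses.get("rmsd")
    if isinstance(rmsd, ReplicateSummary):
        section["rmsd"] = {
            "mean_A": rmsd.mean,
            "sd_A": rmsd.sd,
            "n": rmsd.n,
            "replicate_means_A": list(rmsd.replicate_means),
        }
    fit = analyses.get("binding_fit")
    if isinstance(fit, BindingFit):
        section["binding_fit"] = {
            "model": fit.model,
            "kd_uM": fit.kd_uM,
            "kd_se_uM": fit.kd_se_uM,
            "amplitude": fit.amplitude,
            "identifiable": fit.identifiable,
            "message": fit.message,
        }
    return section


def _comparison_section(comparisons) -> list[dict]:
    out = []
    for label, result in comparisons:
        if not isinstance(result, GroupComparisonResult):
            continue
        out.append(
            {
                "label": label,
                "test": result.test,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "degenerate": result.degenerate,
                "pairwise": [
                    {
                        "pair": list(c.pair),
                        "statistic": c.statistic,
                        "p_raw": c.p_raw,
                        "p_adjusted": c.p_adjusted,
                        "significant": c.p_adjusted < 0.05,
                    }
                    for c in result.pairwise
                ],
            }
        )
    return out


@dataclass(frozen=True)
class SystemsReport:
    data: dict
    markdown: str

    def write(self, json_path=None, md_path=None) -> None:
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.data, fh, indent=2)
        if md_path is not None:
            with open(md_path, "w") as fh:
                fh.write(self.markdown)


def compare_systems_report(bundle: dict, comparisons=None) -> SystemsReport:
    """Build the cross-system report.

    *bundle* maps system labels (e.g. "WT+EET") to dicts of analysis outputs
    under the keys ``binding_site``, ``contact_profile``, ``gate_area``,
    ``crossings``, ``rmsd``, ``binding_fit`` — all optional.  *comparisons*
    is an optional list of ``(label, GroupComparisonResult)`` pairs.
    Systems absent from the bundle are listed as absent.
    """
    labels = [s for s in SYSTEM_ORDER if s in bundle]
    labels += [s for s in bundle if s not in labels]
    systems = {label: _system_section(bundle[label]) for label in labels}
    absent = [s for s in SYSTEM_ORDER if s not in bundle]

    permeating = [
        s for s, sec in systems.items()
        if sec.get("water_crossings", {}).get("up", 0)
        + sec.get("water_crossings", {}).get("down", 0) > 0
    ]
    site_bearing = [s for s, sec in systems.items() if sec.get("binding_site")]

    data = {
        "systems": systems,
        "absent_systems": absent,
        "highlights": {
            "permeating_systems": permeating,
            "site_bearing_systems": site_bearing,
        },
        "comparisons": _comparison_section(comparisons or []),
    }
    data = _jsonable(data)
    return SystemsReport(data=data, markdown=_render_markdown(data))


def _render_markdown(data: dict) -> str:
    lines = ["# Channel system comparison", ""]
    for label, sec in data["systems"].items():
        lines.append(f"## {label}")
        if not sec:
            lines.append("(no analyses supplied)")
        if "binding_site" in sec:
            site = ", ".join(f"{e['subunit']}{e['residue']}" for e in sec["binding_site"])
            lines.append(f"- binding site (> threshold occupancy): {site or 'none'}")
        if "gate_area" in sec:
            g = sec["gate_area"]
            lines.append(
                f"- gate area: {_sig3(g['mean_A2'])} ± {_sig3(g['sd_A2'])} Å²"
            )
            for seg in g.get("segments", []):
                lines.append(
                    f"    - {seg['label']}: {_sig3(seg['mean_A2'])} ± {_sig3(seg['sd_A2'])} Å²"
                )
        if "water_crossings" in sec:
            w = sec["water_crossings"]
            lines.append(f"- water crossings: {w['up']} up / {w['down']} down")
        if "rmsd" in sec:
            r = sec["rmsd"]
            lines.append(
                f"- RMSD: {_sig3(r['mean_A'])} ± {_sig3(r['sd_A'])} Å (n = {r['n']})"
            )
        if "binding_fit" in sec:
            f = sec["binding_fit"]
            if f["identifiable"]:
                lines.append(f"- Kd: {_sig3(f['kd_uM'])} µM ({f['model']})")
            else:
                lines.append(f"- Kd: unidentifiable ({f['message']})")
        lines.append("")
    if data["absent_systems"]:
        lines.append(f"Absent systems: {', '.join(data['absent_systems'])}")
        lines.append("")
    hl = data["highlights"]
    lines.append(
        "Permeating systems: "
        + (", ".join(hl["permeating_systems"]) or "none")
    )
    lines.append(
        "Site-bearing systems: "
        + (", ".join(hl["site_bearing_systems"]) or "none")
    )
    if data["comparisons"]:
        lines.append("")
        lines.append("## Statistical comparisons")
        for c in data["comparisons"]:
            p = c["p_value"]
            head = f"- {c['label']} ({c['test']}): "
            head += "degenerate" if c["degenerate"] else f"p = {_sig3(p)}"
            lines.append(head)
            for pw in c["pairwise"]:
                tag = "" if pw["significant"] else " (n.s.)"
                lines.append(
                    f"    - {pw['pair'][0]} vs {pw['pair'][1]}: "
                    f"adj. p = {_sig3(pw['p_adjusted'])}{tag}"
                )
    lines.append("")
    return "\n".join(lines)
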