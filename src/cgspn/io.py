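"""File formats: JSON model documents, PNML export/import, trajectory CSV.

The canonical model format of this package is a JSON document holding the
full net tuple (color sets, places, transitions with guards as text, arcs
with inscription text, initial marking).  PNML export writes a standard
place/transition PNML skeleton and carries the colored annotations in
``toolspecific`` elements, so any PNML-aware tool sees the net structure
while this package round-trips the full colored model.

Trajectory CSVs are tidy (replicate, time, observable, count) with ``#``
metadata lines embedding the seed, a config hash and the artifact version;
one time unit is 8 h in the immune model.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from lxml import etree

from . import __version__
from .net import Multiset, Net
from .scheduler import ReplicateSummary, Trajectory

__all__ = [
    "net_to_dict",
    "net_from_dict",
    "save_net",
    "load_net",
    "export_pnml",
    "import_pnml",
    "trajectory_frame",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "frame_mean",
    "config_hash",
]

_PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"
_PT_TYPE = "http://www.pnml.org/version-2009/grammar/ptnet"
_TOOL = "cgspn"


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# JSON model documents


def net_to_dict(net: Net) -> dict:
    products = dict(net.products)
    for place in net.places.values():  # anonymous per-place products
        products.setdefault(place.colorset.name, place.colorset)
    for t in net.transitions.values():
        if t.rate_function is not None:
            raise ValueError(
                f"transition {t.name!r} has a Python rate_function; "
                "only rate constants are serializable"
            )
    return {
        "format": "cgspn-net",
        "version": 1,
        "name": net.name,
        "colorsets": [
            {"name": c.name, "values": list(c.values), "circular": c.circular}
            for c in net.colorsets.values()
        ],
        "products": [
            {"name": p.name, "components": [c.name for c in p.components]}
            for p in products.values()
        ],
        "places": [
            {"name": p.name, "colorset": p.colorset.name} for p in net.places.values()
        ],
        "transitions": [
            {
                "name": t.name,
                "kind": t.kind,
                "guard": str(t.guard),
                "rate": t.rate,
                "delay": t.delay,
                "schedule": list(t.schedule) if t.schedule else None,
            }
            for t in net.transitions.values()
        ],
        "arcs": [
            {
                "place": a.place,
                "transition": a.transition,
                "direction": a.direction,
                "pattern": str(a.pattern),
            }
            for a in net.arcs
        ],
        "initial": {
            place: [[list(v), k] for v, k in sorted(ms.items())]
            for place, ms in net.initial.items()
            if ms
        },
    }


def net_from_dict(doc: dict) -> Net:
    if doc.get("format") != "cgspn-net":
        raise ValueError("not a cgspn net document")
    net = Net(doc.get("name", "net"))
    for c in doc["colorsets"]:
        net.add_colorset(c["name"], c["values"], c.get("circular", False))
    for p in doc["products"]:
        net.add_product(p["name"], p["components"])
    for p in doc["places"]:
        net.add_place(p["name"], p["colorset"])
    for t in doc["transitions"]:
        kw = {}
        if t.get("guard") not in (None, "true"):
            kw["guard"] = t["guard"]
        if t.get("rate") is not None:
            kw["rate"] = t["rate"]
        if t.get("delay") is not None:
            kw["delay"] = t["delay"]
        if t.get("schedule") is not None:
            kw["schedule"] = tuple(t["schedule"])
        net.add_transition(t["name"], t["kind"], **kw)
    for a in doc["arcs"]:
        if a["direction"] == "in":
            net.add_input(a["place"], a["transition"], a["pattern"])
        else:
            net.add_output(a["transition"], a["place"], a["pattern"])
    for place, pairs in doc.get("initial", {}).items():
        net.set_initial(place, {tuple(v): k for v, k in pairs})
    return net


def save_net(net: Net, path) -> None:
    Path(path).write_text(json.dumps(net_to_dict(net), indent=1))


def load_net(path) -> Net:
    return net_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# PNML


def _tool(parent) -> etree._Element:
    el = etree.SubElement(parent, f"{{{_PNML_NS}}}toolspecific")
    el.set("tool", _TOOL)
    el.set("version", __version__)
    return el


def _named(parent, tag: str, id_: str, label: str):
    el = etree.SubElement(parent, f"{{{_PNML_NS}}}{tag}")
    el.set("id", id_)
    name = etree.SubElement(el, f"{{{_PNML_NS}}}name")
    etree.SubElement(name, f"{{{_PNML_NS}}}text").text = label
    return el


def export_pnml(net: Net) -> bytes:
    """Serialize to PNML (P/T skeleton + colored toolspecific annotations)."""
    doc = net_to_dict(net)
    root = etree.Element(f"{{{_PNML_NS}}}pnml", nsmap={None: _PNML_NS})
    netel = etree.SubElement(root, f"{{{_PNML_NS}}}net")
    netel.set("id", net.name)
    netel.set("type", _PT_TYPE)
    tool = _tool(netel)
    etree.SubElement(tool, "colorsets").text = json.dumps(doc["colorsets"])
    etree.SubElement(tool, "products").text = json.dumps(doc["products"])
    page = etree.SubElement(netel, f"{{{_PNML_NS}}}page")
    page.set("id", "page0")

    for p in doc["places"]:
        el = _named(page, "place", f"p_{p['name']}", p["name"])
        tool = _tool(el)
        etree.SubElement(tool, "colorset").text = p["colorset"]
        initial = doc["initial"].get(p["name"])
        if initial:
            etree.SubElement(tool, "initialMarking").text = json.dumps(initial)
    for t in doc["transitions"]:
        el = _named(page, "transition", f"t_{t['name']}", t["name"])
        tool = _tool(el)
        etree.SubElement(tool, "kind").text = t["kind"]
        etree.SubElement(tool, "guard").text = t["guard"]
        for key in ("rate", "delay", "schedule"):
            if t[key] is not None:
                etree.SubElement(tool, key).text = json.dumps(t[key])
    for i, a in enumerate(doc["arcs"]):
        el = etree.SubElement(page, f"{{{_PNML_NS}}}arc")
        el.set("id", f"a{i}")
        if a["direction"] == "in":
            el.set("source", f"p_{a['place']}")
            el.set("target", f"t_{a['transition']}")
        else:
            el.set("source", f"t_{a['transition']}")
            el.set("target", f"p_{a['place']}")
        tool = _tool(el)
        etree.SubElement(tool, "pattern").text = a["pattern"]
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _tool_of(el):
    for sub in el.findall(f"{{{_PNML_NS}}}toolspecific"):
        if sub.get("tool") == _TOOL:
            return sub
    return None


def _ts_text(tool, tag: str):
    """Text of a toolspecific child, with or without the PNML namespace."""
    text = tool.findtext(tag)
    if text is None:
        text = tool.findtext(f"{{{_PNML_NS}}}{tag}")
    return text


def import_pnml(data: Union[bytes, str, Path]) -> Net:
    """Read back this package's PNML dialect (round-trips export_pnml)."""
    if isinstance(data, Path) or (isinstance(data, str) and "\n" not in data and Path(data).exists()):
        data = Path(data).read_bytes()
    if isinstance(data, str):
        data = data.encode()
    root = etree.fromstring(data)
    netel = root.find(f"{{{_PNML_NS}}}net")
    if netel is None:
        raise ValueError("no <net> element in PNML document")
    tool = _tool_of(netel)
    if tool is None:
        raise ValueError("PNML document lacks cgspn toolspecific annotations")
    doc = {
        "format": "cgspn-net",
        "version": 1,
        "name": netel.get("id", "net"),
        "colorsets": json.loads(_ts_text(tool, "colorsets")),
        "products": json.loads(_ts_text(tool, "products")),
        "places": [],
        "transitions": [],
        "arcs": [],
        "initial": {},
    }
    page = netel.find(f"{{{_PNML_NS}}}page")
    for el in page.findall(f"{{{_PNML_NS}}}place"):
        name = el.findtext(f"{{{_PNML_NS}}}name/{{{_PNML_NS}}}text")
        tool = _tool_of(el)
        doc["places"].append({"name": name, "colorset": _ts_text(tool, "colorset")})
        init = _ts_text(tool, "initialMarking")
        if init:
            doc["initial"][name] = json.loads(init)
    for el in page.findall(f"{{{_PNML_NS}}}transition"):
        name = el.findtext(f"{{{_PNML_NS}}}name/{{{_PNML_NS}}}text")
        tool = _tool_of(el)
        entry = {"name": name, "kind": _ts_text(tool, "kind"), "guard": _ts_text(tool, "guard")}
        for key in ("rate", "delay", "schedule"):
            text = _ts_text(tool, key)
            entry[key] = json.loads(text) if text is not None else None
        doc["transitions"].append(entry)
    ids = {f"p_{p['name']}": ("place", p["name"]) for p in doc["places"]}
    ids.update({f"t_{t['name']}": ("transition", t["name"]) for t in doc["transitions"]})
    for el in page.findall(f"{{{_PNML_NS}}}arc"):
        src, dst = ids[el.get("source")], ids[el.get("target")]
        tool = _tool_of(el)
        pattern = _ts_text(tool, "pattern")
        if src[0] == "place":
            doc["arcs"].append(
                {"place": src[1], "transition": dst[1], "direction": "in", "pattern": pattern}
            )
        else:
            doc["arcs"].append(
                {"place": dst[1], "transition": src[1], "direction": "out", "pattern": pattern}
            )
    return net_from_dict(doc)


# ---------------------------------------------------------------------------
# trajectory CSV


def trajectory_frame(obj: Union[Trajectory, ReplicateSummary]) -> pd.DataFrame:
    """Tidy (replicate, time, observable, count) frame."""
    rows = []
    if isinstance(obj, Trajectory):
        items = {obj.replicate: obj.counts}
        times = obj.times
    else:
        times = obj.times
        items = {
            i: {name: obj.counts[name][i] for name in obj.counts}
            for i in range(obj.n)
        }
    frames = []
    for rep, counts in items.items():
        for name, series in counts.items():
            frames.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "time": times,
                        "observable": name,
                        "count": series,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["replicate", "time", "observable", "count"])
    return pd.concat(frames, ignore_index=True)


_CSV_COLUMNS = ["replicate", "time", "observable", "count"]


def write_trajectory_csv(obj, path, meta: Optional[dict] = None) -> None:
    """Tidy CSV with ``#`` metadata header (seed, config hash, version).

    The time column is in simulation time units (1 unit = 8 h in the
    immune model).
    """
    meta = dict(meta or {})
    meta.setdefault("artifact_version", __version__)
    meta.setdefault("time_unit", "1 step = 8 h")
    if isinstance(obj, Trajectory):
        meta.setdefault("seed", obj.seed)
    elif isinstance(obj, ReplicateSummary):
        meta.setdefault("seeds", ",".join(str(s) for s in obj.seeds))
    df = trajectory_frame(obj) if not isinstance(obj, pd.DataFrame) else obj
    with open(path, "w") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}={meta[key]}\n")
        df.to_csv(fh, index=False, columns=_CSV_COLUMNS)


def read_trajectory_csv(path):
    """Read a trajectory CSV; returns ``(DataFrame, metadata dict)``."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV misses column(s): {', '.join(missing)}")
    return df, meta


def frame_mean(df: pd.DataFrame):
    """Mean-over-replicates trajectories from a tidy frame.

    Returns ``(times, {observable: mean array})``, the inputs the response
    summarizer consumes.
    """
    wide = df.pivot_table(index="time", columns="observable", values="count", aggfunc="mean")
    times = wide.index.to_numpy()
    return times, {name: wide[name].to_numpy() for name in wide.columns}
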