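"""Declarative analysis configuration with lossless XML round-tripping.

The XML schema is defined by this package (versioned via the
``schema_version`` attribute). It is deliberately flat and hand-editable:
every pipeline choice — channel/marker matching, calibration, ROI,
preprocessing chain, segmentation options, per-marker resize/foci
settings, relevance filters, cell-type definitions, report options — is an
element or attribute, so a batch run is fully described by one file.

Constraint bounds may be numeric literals or per-image quartile references
of the form ``Q1(M1.area)`` / ``Q2(...)`` / ``Q3(...)``, resolved against
the relevant cells of each image at classification time. This is how
quartile-based typing recipes ("area in the Q4 quartile") stay adaptive
per image in batch mode.
"""

from __future__ import annotations

import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from celltyper.features import INTENSITY_FEATURES, SHAPE_FEATURES
from celltyper.imgio import Calibration, MarkerRole
from celltyper.preprocess import PREPROCESS_OPS, PreprocessStep
from celltyper.thresholds import THRESHOLD_METHODS

__all__ = [
    "AnalysisConfig",
    "ROISpec",
    "MarkerMeasureSpec",
    "ConstraintSpec",
    "CellTypeSpec",
    "ReportSpec",
    "save_config",
    "load_config",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"

_QUARTILE_RE = re.compile(r"^(Q[123])\(([^)]+)\)$")


def _parse_bound(text: str, default: float) -> float | str:
    if text is None or text == "":
        return default
    if _QUARTILE_RE.match(text):
        return text
    return float(text)


def _fmt_bound(value: float | str) -> str:
    if isinstance(value, str):
        return value
    if value == -math.inf:
        return "-inf"
    if value == math.inf:
        return "inf"
    return repr(value)


@dataclass
class ROISpec:
    """Region-of-interest geometry; rasterized to a mask at run time."""

    type: str = "none"  # none | rectangle | ellipse | polygon
    x: float = 0.0
    y: float = 0.0
    w: float = 0.0
    h: float = 0.0
    cx: float = 0.0
    cy: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    points: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class MarkerMeasureSpec:
    """Measurement settings for Marker II or III."""

    resize_mode: str = "none"
    resize_radius: int = 1
    foci_enabled: bool = False
    foci_tolerance: float = 30.0
    presmooth_sigma: float = 0.0


@dataclass
class ConstraintSpec:
    """Config-level constraint; bounds may be quartile references."""

    feature: str | None = None
    min: float | str = -math.inf
    max: float | str = math.inf
    left_feature: str | None = None
    relation: str | None = None
    right_feature: str | None = None

    @property
    def is_comparison(self) -> bool:
        return self.feature is None

    def referenced_features(self) -> list[str]:
        feats = []
        if self.is_comparison:
            feats += [self.left_feature, self.right_feature]
        else:
            feats.append(self.feature)
            for bound in (self.min, self.max):
                m = _QUARTILE_RE.match(bound) if isinstance(bound, str) else None
                if m:
                    feats.append(m.group(2))
        return feats


@dataclass
class CellTypeSpec:
    name: str
    constraints: list[ConstraintSpec]
    color: tuple[int, int, int] = (255, 0, 0)


@dataclass
class FilterSpec:
    feature: str
    min: float = -math.inf
    max: float = math.inf


@dataclass
class ReportSpec:
    scatter_x: str | None = None
    scatter_y: str | None = None
    quadrants_x: str | None = None
    quadrants_y: str | None = None
    quadrants_thr_x: float | str | None = None
    quadrants_thr_y: float | str | None = None
    fit_model: str | None = None
    fit_degree: int = 2


@dataclass
class AnalysisConfig:
    """Complete, XML-serializable description of one analysis."""

    channels: dict[str, int] = field(default_factory=lambda: {"markerI": 0})
    calibration: Calibration = field(default_factory=Calibration)
    roi: ROISpec = field(default_factory=ROISpec)
    preprocess: list[PreprocessStep] = field(default_factory=list)
    segment_method: str = "Otsu"
    watershed: bool = False
    fill_holes: bool = False
    dark_background: bool = True
    markerII: MarkerMeasureSpec = field(default_factory=MarkerMeasureSpec)
    markerIII: MarkerMeasureSpec = field(default_factory=MarkerMeasureSpec)
    filters: list[FilterSpec] = field(default_factory=list)
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    report: ReportSpec = field(default_factory=ReportSpec)
    schema_version: str = SCHEMA_VERSION

    # ----- validation ------------------------------------------------

    def mapped_roles(self) -> dict[str, MarkerRole]:
        roles = {
            "markerI": MarkerRole.MARKER_I,
            "markerII": MarkerRole.MARKER_II,
            "markerIII": MarkerRole.MARKER_III,
        }
        return {k: roles[k] for k in self.channels}

    def valid_feature_names(self) -> set[str]:
        names: set[str] = {"cell_id"}
        names.update(f"M1.{f}" for f in SHAPE_FEATURES + INTENSITY_FEATURES)
        for key, prefix in (("markerII", "M2"), ("markerIII", "M3")):
            if key in self.channels:
                names.update(f"{prefix}.{f}" for f in INTENSITY_FEATURES)
                spec: MarkerMeasureSpec = getattr(self, key)
                if spec.foci_enabled:
                    names.add(f"{prefix}.foci_count")
        return names

    def validate(self) -> None:
        if "markerI" not in self.channels:
            raise ValueError("config must map markerI to a channel")
        idxs = list(self.channels.values())
        if len(idxs) != len(set(idxs)):
            raise ValueError("duplicate channel index in marker mapping")
        if self.segment_method not in THRESHOLD_METHODS:
            raise ValueError(
                f"unknown segment.method '{self.segment_method}'; valid: "
                + ", ".join(sorted(THRESHOLD_METHODS))
            )
        if self.roi.type not in ("none", "rectangle", "ellipse", "polygon"):
            raise ValueError(f"unknown roi.type '{self.roi.type}'")
        for i, step in enumerate(self.preprocess):
            if step.op not in PREPROCESS_OPS:
                raise ValueError(f"preprocess step {i}: unknown op '{step.op}'")
        valid = self.valid_feature_names()
        for f in self.filters:
            if not f.feature.startswith("M1."):
                raise ValueError(
                    f"relevance filter feature '{f.feature}' must be a Marker I feature"
                )
            if f.feature not in valid:
                raise ValueError(
                    f"unknown filter feature '{f.feature}'; valid names: "
                    + ", ".join(sorted(valid))
                )
        seen = set()
        for ct in self.cell_types:
            if ct.name in seen:
                raise ValueError(f"duplicate cell type name '{ct.name}'")
            seen.add(ct.name)
            if not ct.constraints:
                raise ValueError(f"cell type '{ct.name}' has no constraints")
            for c in ct.constraints:
                for feat in c.referenced_features():
                    if feat not in valid:
                        raise ValueError(
                            f"cell type '{ct.name}': unknown or unavailable feature "
                            f"'{feat}' (is its marker channel mapped and foci enabled?); "
                            "valid names: " + ", ".join(sorted(valid))
                        )
        for feat in (self.report.scatter_x, self.report.scatter_y,
                     self.report.quadrants_x, self.report.quadrants_y):
            if feat is not None and feat not in valid:
                raise ValueError(f"report references unknown feature '{feat}'")
        if self.report.fit_model is not None and self.report.fit_model not in (
            "linear", "polynomial", "power", "logarithmic", "exponential"
        ):
            raise ValueError(f"unknown fit model '{self.report.fit_model}'")


# ---------------------------------------------------------------------------
# XML serialization


def _bool(v: bool) -> str:
    return "true" if v else "false"


def _parse_bool(text: str, where: str) -> bool:
    if text == "true":
        return True
    if text == "false":
        return False
    raise ValueError(f"{where}: expected 'true' or 'false', got '{text}'")


def config_to_xml(config: AnalysisConfig) -> ET.Element:
    root = ET.Element("celltyper-config", schema_version=config.schema_version)
    ET.SubElement(root, "channels", {k: str(v) for k, v in config.channels.items()})
    cal = config.calibration
    ET.SubElement(root, "calibration", {
        "pixel_width": repr(cal.pixel_width), "pixel_height": repr(cal.pixel_height),
        "unit": cal.unit, "calibrated": _bool(cal.calibrated),
    })
    roi = config.roi
    roi_el = ET.SubElement(root, "roi", {"type": roi.type})
    if roi.type == "rectangle":
        roi_el.attrib.update(x=repr(roi.x), y=repr(roi.y), w=repr(roi.w), h=repr(roi.h))
    elif roi.type == "ellipse":
        roi_el.attrib.update(cx=repr(roi.cx), cy=repr(roi.cy), rx=repr(roi.rx), ry=repr(roi.ry))
    elif roi.type == "polygon":
        roi_el.set("points", " ".join(f"{x},{y}" for x, y in roi.points))
    pre = ET.SubElement(root, "preprocess")
    for step in config.preprocess:
        s = ET.SubElement(pre, "step", {"op": step.op})
        for name, value in step.params.items():
            ET.SubElement(s, "param", {"name": name, "value": repr(float(value))})
    ET.SubElement(root, "segment", {
        "method": config.segment_method,
        "watershed": _bool(config.watershed),
        "fill_holes": _bool(config.fill_holes),
        "dark_background": _bool(config.dark_background),
    })
    for key in ("markerII", "markerIII"):
        spec: MarkerMeasureSpec = getattr(config, key)
        m = ET.SubElement(root, key)
        ET.SubElement(m, "resize", {"mode": spec.resize_mode, "radius": str(spec.resize_radius)})
        ET.SubElement(m, "foci", {
            "enabled": _bool(spec.foci_enabled),
            "tolerance": repr(spec.foci_tolerance),
            "presmooth_sigma": repr(spec.presmooth_sigma),
        })
    filt = ET.SubElement(root, "filters")
    for f in config.filters:
        ET.SubElement(filt, "filter", {
            "feature": f.feature, "min": _fmt_bound(f.min), "max": _fmt_bound(f.max),
        })
    types = ET.SubElement(root, "cell_types")
    for ct in config.cell_types:
        t = ET.SubElement(types, "cell_type", {
            "name": ct.name, "color": ",".join(str(c) for c in ct.color),
        })
        for c in ct.constraints:
            if c.is_comparison:
                ET.SubElement(t, "constraint", {
                    "left": c.left_feature, "relation": c.relation, "right": c.right_feature,
                })
            else:
                ET.SubElement(t, "constraint", {
                    "feature": c.feature, "min": _fmt_bound(c.min), "max": _fmt_bound(c.max),
                })
    rep = ET.SubElement(root, "report")
    r = config.report
    if r.scatter_x and r.scatter_y:
        ET.SubElement(rep, "scatter", {"x": r.scatter_x, "y": r.scatter_y})
    if r.quadrants_x and r.quadrants_y:
        ET.SubElement(rep, "quadrants", {
            "x": r.quadrants_x, "y": r.quadrants_y,
            "thr_x": _fmt_bound(r.quadrants_thr_x), "thr_y": _fmt_bound(r.quadrants_thr_y),
        })
    if r.fit_model:
        ET.SubElement(rep, "fit", {"model": r.fit_model, "degree": str(r.fit_degree)})
    return root


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    """Validate and write the configuration as human-readable XML."""
    config.validate()
    root = config_to_xml(config)
    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(str(path), encoding="unicode", xml_declaration=True)
    with open(path, "a") as fh:
        fh.write("\n")


_EXPECTED_CHILDREN = {
    "channels", "calibration", "roi", "preprocess", "segment",
    "markerII", "markerIII", "filters", "cell_types", "report",
}


def _check_attrs(el: ET.Element, allowed: set[str], where: str) -> None:
    unknown = set(el.attrib) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown attribute(s) {sorted(unknown)}")


def config_from_xml(root: ET.Element) -> AnalysisConfig:
    if root.tag != "celltyper-config":
        raise ValueError(f"root element must be 'celltyper-config', got '{root.tag}'")
    version = root.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema_version '{version}' (this build reads {SCHEMA_VERSION})"
        )
    config = AnalysisConfig()
    seen = set()
    for el in root:
        if el.tag not in _EXPECTED_CHILDREN:
            raise ValueError(f"unknown element '{el.tag}' under celltyper-config")
        if el.tag in seen:
            raise ValueError(f"duplicate element '{el.tag}'")
        seen.add(el.tag)
        if el.tag == "channels":
            _check_attrs(el, {"markerI", "markerII", "markerIII"}, "channels")
            config.channels = {k: int(v) for k, v in el.attrib.items()}
        elif el.tag == "calibration":
            _check_attrs(el, {"pixel_width", "pixel_height", "unit", "calibrated"}, "calibration")
            config.calibration = Calibration(
                pixel_width=float(el.get("pixel_width", "1")),
                pixel_height=float(el.get("pixel_height", "1")),
                unit=el.get("unit", "pixel"),
                calibrated=_parse_bool(el.get("calibrated", "false"), "calibration"),
            )
        elif el.tag == "roi":
            _check_attrs(el, {"type", "x", "y", "w", "h", "cx", "cy", "rx", "ry", "points"}, "roi")
            roi = ROISpec(type=el.get("type", "none"))
            for attr in ("x", "y", "w", "h", "cx", "cy", "rx", "ry"):
                if el.get(attr) is not None:
                    setattr(roi, attr, float(el.get(attr)))
            if el.get("points"):
                roi.points = [
                    tuple(float(p) for p in pair.split(","))
                    for pair in el.get("points").split()
                ]
            config.roi = roi
        elif el.tag == "preprocess":
            steps = []
            for i, s in enumerate(el):
                if s.tag != "step":
                    raise ValueError(f"preprocess: unknown element '{s.tag}'")
                _check_attrs(s, {"op"}, f"preprocess step {i}")
                params = {}
                for p in s:
                    if p.tag != "param":
                        raise ValueError(f"preprocess step {i}: unknown element '{p.tag}'")
                    params[p.get("name")] = float(p.get("value"))
                steps.append(PreprocessStep(op=s.get("op", ""), params=params))
            config.preprocess = steps
        elif el.tag == "segment":
            _check_attrs(el, {"method", "watershed", "fill_holes", "dark_background"}, "segment")
            config.segment_method = el.get("method", "Otsu")
            config.watershed = _parse_bool(el.get("watershed", "false"), "segment.watershed")
            config.fill_holes = _parse_bool(el.get("fill_holes", "false"), "segment.fill_holes")
            config.dark_background = _parse_bool(
                el.get("dark_background", "true"), "segment.dark_background"
            )
        elif el.tag in ("markerII", "markerIII"):
            spec = MarkerMeasureSpec()
            for s in el:
                if s.tag == "resize":
                    _check_attrs(s, {"mode", "radius"}, f"{el.tag}.resize")
                    spec.resize_mode = s.get("mode", "none")
                    spec.resize_radius = int(s.get("radius", "1"))
                elif s.tag == "foci":
                    _check_attrs(s, {"enabled", "tolerance", "presmooth_sigma"}, f"{el.tag}.foci")
                    spec.foci_enabled = _parse_bool(s.get("enabled", "false"), f"{el.tag}.foci")
                    spec.foci_tolerance = float(s.get("tolerance", "30"))
                    spec.presmooth_sigma = float(s.get("presmooth_sigma", "0"))
                else:
                    raise ValueError(f"{el.tag}: unknown element '{s.tag}'")
            setattr(config, el.tag, spec)
        elif el.tag == "filters":
            filters = []
            for s in el:
                if s.tag != "filter":
                    raise ValueError(f"filters: unknown element '{s.tag}'")
                _check_attrs(s, {"feature", "min", "max"}, "filter")
                filters.append(FilterSpec(
                    feature=s.get("feature", ""),
                    min=float(s.get("min", "-inf")),
                    max=float(s.get("max", "inf")),
                ))
            config.filters = filters
        elif el.tag == "cell_types":
            types = []
            for t in el:
                if t.tag != "cell_type":
                    raise ValueError(f"cell_types: unknown element '{t.tag}'")
                _check_attrs(t, {"name", "color"}, "cell_type")
                color = tuple(int(c) for c in t.get("color", "255,0,0").split(","))
                constraints = []
                for c in t:
                    if c.tag != "constraint":
                        raise ValueError(
                            f"cell_type '{t.get('name')}': unknown element '{c.tag}'"
                        )
                    if c.get("feature") is not None:
                        _check_attrs(c, {"feature", "min", "max"}, "constraint")
                        constraints.append(ConstraintSpec(
                            feature=c.get("feature"),
                            min=_parse_bound(c.get("min"), -math.inf),
                            max=_parse_bound(c.get("max"), math.inf),
                        ))
                    else:
                        _check_attrs(c, {"left", "relation", "right"}, "constraint")
                        constraints.append(ConstraintSpec(
                            left_feature=c.get("left"),
                            relation=c.get("relation"),
                            right_feature=c.get("right"),
                        ))
                types.append(CellTypeSpec(
                    name=t.get("name", ""), constraints=constraints, color=color
                ))
            config.cell_types = types
        elif el.tag == "report":
            rep = ReportSpec()
            for s in el:
                if s.tag == "scatter":
                    _check_attrs(s, {"x", "y"}, "report.scatter")
                    rep.scatter_x, rep.scatter_y = s.get("x"), s.get("y")
                elif s.tag == "quadrants":
                    _check_attrs(s, {"x", "y", "thr_x", "thr_y"}, "report.quadrants")
                    rep.quadrants_x, rep.quadrants_y = s.get("x"), s.get("y")
                    rep.quadrants_thr_x = _parse_bound(s.get("thr_x"), math.inf)
                    rep.quadrants_thr_y = _parse_bound(s.get("thr_y"), math.inf)
                elif s.tag == "fit":
                    _check_attrs(s, {"model", "degree"}, "report.fit")
                    rep.fit_model = s.get("model")
                    rep.fit_degree = int(s.get("degree", "2"))
                else:
                    raise ValueError(f"report: unknown element '{s.tag}'")
            config.report = rep
    config.validate()
    return config


def load_config(path: str | Path) -> AnalysisConfig:
    """Parse and validate an XML configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML in {path}: {exc}") from exc
    return config_from_xml(tree.getroot())
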