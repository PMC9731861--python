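"""Hierarchical evaluation pipeline, slide reports, and overlay export.

Evaluation order: (1) slide QC -- a flagged slide is routed to manual
review and gets no lesion analysis; (2) the melanocytic module
(patch -> probmap -> ROIs -> MIL); a positive melanocytic call adds
subtype and margin status and stops the cascade; (3) otherwise BCC and
ASL both run, a joint positive resolving to the line with the higher
slide probability (tie -> BCC, configurable); (4) otherwise, and only
for non-excision specimens, the benign modules SK and VV run; (5) the
report assembles per-line calls, ROI overlay data, and a config/seed
fingerprint. Every model invocation is recorded in a structured call
log so the short-circuiting rules are auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .config import SEVERITY_LADDERS
from .margin import InkThresholds, MarginStatus, margin_map_from_slide, margin_status
from .patches import ProbabilityMap
from .qc import HybridQCClassifier, QCReport, classify_section, qc_slide
from .roi import Roi, extract_embeddings
from .segmentation import extract_sections, segment_tissue
from .slide_io import PatchGrid, SlideImage
from .subtype import SeverityLadder, SubtypeResult, expand_roi_to_lesion, subtype_cascade
from .training import LineModels, slide_rois


class CallLog:
    """Structured JSON-lines log of every model call."""

    def __init__(self):
        self.entries: list[dict] = []

    def record(self, event: str, **kw) -> None:
        self.entries.append({"event": event, **kw})

    def count(self, event: str, **filters) -> int:
        return sum(1 for e in self.entries
                   if e["event"] == event and
                   all(e.get(k) == v for k, v in filters.items()))

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e) + "\n")


@dataclass
class LineCall:
    """Result of one lesion line's multi-level analysis on one slide."""

    line: str
    prob: float
    call: bool
    rois: list[Roi] = field(default_factory=list)
    attention: np.ndarray | None = None
    pmap: ProbabilityMap | None = None
    rescaled: SlideImage | None = None


@dataclass
class SlideReport:
    wsi_name: str
    qc: QCReport | None = None
    routed_manual: bool = False
    line_results: dict = field(default_factory=dict)   # line -> {prob, call}
    final_line: str | None = None
    subtype: str | None = None
    margin: MarginStatus | None = None
    rois: list[Roi] = field(default_factory=list)
    attention: list[float] = field(default_factory=list)
    benign_positives: list[str] = field(default_factory=list)
    roi_size: int = 0
    mpp_scale: float = 1.0     # rescaled-slide -> level-0 pixel factor
    fingerprint: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "wsi_name": self.wsi_name,
            "qc": None if self.qc is None else {
                "section_labels": self.qc.section_labels,
                "bad_fraction": self.qc.bad_fraction,
                "flagged": self.qc.flagged},
            "routed_manual": self.routed_manual,
            "line_results": self.line_results,
            "final_line": self.final_line,
            "subtype": self.subtype,
            "margin": None if self.margin is None else {
                "status": self.margin.status,
                "overlap_patches": self.margin.overlap_patches},
            "rois": [{"center": r.center, "window": r.window,
                      "label": r.label} for r in self.rois],
            "attention": list(map(float, self.attention)),
            "benign_positives": self.benign_positives,
            "fingerprint": self.fingerprint,
        }


def resolve_conflict(bcc_prob: float, bcc_call: bool, asl_prob: float,
                     asl_call: bool, tie_break: str = "bcc") -> str | None:
    """Final line when BCC and ASL ran jointly.

    Both positive -> the higher slide probability wins; an exact tie
    goes to the configured tie-break line (default BCC).
    """
    if bcc_call and asl_call:
        if bcc_prob > asl_prob:
            return "bcc"
        if asl_prob > bcc_prob:
            return "asl"
        return tie_break
    if bcc_call:
        return "bcc"
    if asl_call:
        return "asl"
    return None


def _run_real_line(slide: SlideImage, lm: LineModels) -> LineCall:
    rois, images, cleaned, rescaled = slide_rois(slide, lm.cfg, lm.patch)
    bag = extract_embeddings(lm.roi, images, slide.name, 0, rois)
    prob, call, att = lm.mil.predict_wsi(bag.matrix)
    return LineCall(line=lm.line, prob=prob, call=call, rois=rois,
                    attention=att, pmap=cleaned, rescaled=rescaled)


def _subtype_for(result: LineCall, subtypers: dict, roi_size: int,
                 call_log: CallLog, roi_threshold: float = 0.5
                 ) -> SubtypeResult | None:
    if result.pmap is None or result.rescaled is None:
        return None
    if result.line not in SEVERITY_LADDERS or result.line not in subtypers:
        return None
    ladder = SeverityLadder(result.line)
    expanded = []
    for roi in result.rois:
        x0, y0, x1, y1 = expand_roi_to_lesion(roi, result.pmap)
        crop = result.rescaled.pixels[y0:y1, x0:x1]
        if crop.size == 0:
            continue
        expanded.append(np.clip(np.round(resize(
            crop.astype(float), (roi_size, roi_size), order=1,
            anti_aliasing=False, preserve_range=True)), 0, 255
        ).astype(np.uint8))
    if not expanded:
        return None

    counting = {}
    for name, clf in subtypers[result.line].items():
        def make(nm, c):
            def scorer(images):
                call_log.record("subtype_model", line=result.line, subtype=nm)
                if hasattr(c, "predict_proba"):
                    return c.predict_proba(images)
                return c(images)
            return scorer
        counting[name] = make(name, clf)
    return subtype_cascade(np.stack(expanded), ladder, counting,
                           roi_threshold=roi_threshold)


def evaluate_slide(slide: SlideImage, models: dict,
                   specimen_excision: bool = False,
                   qc_model: HybridQCClassifier | None = None,
                   segmenter=None,
                   subtypers: dict | None = None,
                   ink_thresholds: InkThresholds | None = None,
                   call_log: CallLog | None = None,
                   seed: int = 0,
                   tie_break: str = "bcc") -> SlideReport:
    """Run the full hierarchical cascade on one slide.

    ``models`` maps each required line to a trained ``LineModels`` stack
    or to a callable ``slide -> LineCall`` (stub support for pipeline
    audits). Missing models for a line the hierarchy needs raise.
    """
    call_log = call_log if call_log is not None else CallLog()
    subtypers = subtypers or {}
    report = SlideReport(wsi_name=slide.name,
                         fingerprint={"seed": seed,
                                      "excision": specimen_excision})
    rng = np.random.default_rng(seed)

    if qc_model is not None:
        mask = segment_tissue(slide, segmenter)
        sections = extract_sections(mask)
        if sections:
            labels = [classify_section(s.crop(slide.pixels), qc_model)
                      for s in sections]
            call_log.record("qc", n_sections=len(sections))
            report.qc = qc_slide(labels)
            if report.qc.flagged:
                report.routed_manual = True
                return report

    def run(line: str) -> LineCall:
        if line not in models:
            raise KeyError(f"no model for required line {line!r}")
        call_log.record("line_model", line=line)
        m = models[line]
        res = m(slide) if callable(m) else _run_real_line(slide, m)
        report.line_results[line] = {"prob": res.prob, "call": bool(res.call)}
        return res

    def finalize_positive(res: LineCall):
        report.final_line = res.line
        report.rois = res.rois
        if res.attention is not None:
            report.attention = list(map(float, res.attention))
        if isinstance(models.get(res.line), LineModels):
            report.roi_size = models[res.line].cfg.roi_size
            report.mpp_scale = (models[res.line].cfg.base_mpp / slide.mpp
                                if slide.mpp else 1.0)
        st = _subtype_for(res, subtypers, report.roi_size or 64, call_log)
        if st is not None:
            report.subtype = st.label
        if res.pmap is not None and res.rescaled is not None:
            grid = PatchGrid(patch_size=res.pmap.patch_size,
                             slide_height=res.pmap.slide_shape[0],
                             slide_width=res.pmap.slide_shape[1])
            mmap = margin_map_from_slide(res.rescaled.pixels, grid,
                                         ink_thresholds)
            report.margin = margin_status(res.pmap, mmap, res.line,
                                          report.subtype)

    mel = run("mel")
    if mel.call:
        finalize_positive(mel)
        return report

    bcc = run("bcc")
    asl = run("asl")
    final = resolve_conflict(bcc.prob, bcc.call, asl.prob, asl.call,
                             tie_break=tie_break)
    if final is not None:
        finalize_positive(bcc if final == "bcc" else asl)
        return report

    if not specimen_excision:
        sk = run("sk")
        vv = run("vv")
        positives = [r for r in (sk, vv) if r.call]
        report.benign_positives = [r.line for r in positives]
        if positives:
            best = max(positives, key=lambda r: r.prob)
            report.final_line = best.line
            report.rois = best.rois
            if best.attention is not None:
                report.attention = list(map(float, best.attention))
            if isinstance(models.get(best.line), LineModels):
                report.roi_size = models[best.line].cfg.roi_size
    return report


def export_overlay(report: SlideReport, path: str | Path) -> None:
    """GeoJSON overlay: one circle feature per ROI (center in level-0
    pixel coordinates, radius = roi_size/2) plus a separate feature
    layer of margin-overlap patches."""
    f = report.mpp_scale or 1.0
    radius = (report.roi_size or 0) / 2.0 * f
    features = []
    att = report.attention or [None] * len(report.rois)
    for roi, a in zip(report.rois, att):
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [roi.center[0] * f,
                                         roi.center[1] * f]},
            "properties": {"layer": "roi", "radius": radius,
                           "line": report.final_line,
                           "subtype": report.subtype,
                           "margin": (report.margin.status
                                      if report.margin else None),
                           "attention": a},
        })
    if report.margin is not None:
        for (r, c) in report.margin.overlap_patches:
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [c, r]},
                "properties": {"layer": "margin_overlap", "grid_row": r,
                               "grid_col": c},
            })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  indent=2)


def load_overlay(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
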