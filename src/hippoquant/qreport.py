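"""Per-subject quantitative report (QReport) assembly and rendering.

The report is JSON-first: :class:`QReportDoc` is the document of record
(demographics, fit QC, global metrics with reference ranges, long-axis
profiles with normative bands, machine-advice flags, snapshot references,
pipeline and model provenance), serialising losslessly. HTML is a pure view:
every number shown is taken from the document (display-rounded: ratios and
qT2 to 1 decimal, volumes to whole mm3), and the profile figures are
regenerated deterministically from the document's arrays — the subject
curve in black over the normative mean +/- 1.96 SD band in blue, posterior
to anterior.
"""

from __future__ import annotations

import base64
import html as _html
import io
import json
import math
from dataclasses import dataclass, field

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy import ndimage

from .imaging_io import LabelMask, Volume3D, assert_same_grid
from .morphometry_profiles import GlobalMetrics, HippocampusProfile
from .normative_model import FlagSet, NormativeModel
from .qt2_mapping import FitQC

__all__ = ["QReportDoc", "assemble_report", "render_html", "render_snapshots", "save_snapshots"]

PIPELINE_VERSION = "hippoquant 0.1.0"

REQUIRED_META = ("age", "gender", "scan_date", "scanner", "hospital")

_METRIC_LABELS = {
    "vol_left": ("Left hippocampal volume", "mm3", 0),
    "vol_right": ("Right hippocampal volume", "mm3", 0),
    "qt2_left": ("Left hippocampal qT2", "ms", 1),
    "qt2_right": ("Right hippocampal qT2", "ms", 1),
    "lr_vol_ratio_pct": ("L:R volume ratio", "%", 1),
    "lr_qt2_ratio_pct": ("L:R qT2 ratio", "%", 1),
}


@dataclass
class QReportDoc:
    """Structured quantitative report; serialises losslessly to JSON."""

    meta: dict
    qc: dict
    global_entries: list[dict]  # metric, value, lo, hi (lo/hi None = no reference)
    profiles: dict  # side -> {positions, area_mm2, qt2_ms, bands{metric -> lo/hi arrays|None}}
    flags: dict  # {"flags": {...}, "overall": str}
    snapshots: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.__dict__, indent=1, sort_keys=True, allow_nan=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "QReportDoc":
        try:
            doc = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(**doc)


def _clean(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return float(x)


def assemble_report(
    meta: dict,
    metrics: GlobalMetrics,
    profiles: dict[str, HippocampusProfile],
    model: NormativeModel,
    qc: FitQC | dict,
    flags: FlagSet,
    snapshots: list[str] | None = None,
) -> QReportDoc:
    """Assemble the document; deterministic for fixed inputs.

    Raw (unrounded) values are stored; rounding happens only at display
    time. Raises when a mandatory demographic field is missing or the model
    carries no provenance.
    """
    missing = [k for k in REQUIRED_META if k not in meta or meta[k] in (None, "")]
    if missing:
        raise ValueError(f"missing mandatory meta fields: {', '.join(missing)}")
    if not model.provenance:
        raise ValueError("normative model carries no provenance")

    global_entries = []
    for name in _METRIC_LABELS:
        entry = model.entries.get(name)
        global_entries.append(
            {
                "metric": name,
                "value": float(getattr(metrics, name)),
                "lo": _clean(entry.lo) if entry else None,
                "hi": _clean(entry.hi) if entry else None,
            }
        )

    prof_doc = {}
    for side, prof in profiles.items():
        bands = {}
        for metric in ("area_mm2", "qt2_ms"):
            ref = model.profiles.get(side, {}).get(metric)
            if ref is None:
                bands[metric] = None
            else:
                lo = ref["mean"] - 1.96 * ref["sd"]
                hi = ref["mean"] + 1.96 * ref["sd"]
                bands[metric] = {"lo": [_clean(x) for x in lo], "hi": [_clean(x) for x in hi]}
        prof_doc[side] = {
            "positions": [float(p) for p in prof.positions],
            "area_mm2": [_clean(a) for a in prof.area_mm2],
            "qt2_ms": [_clean(q) for q in prof.qt2_ms],
            "bands": bands,
        }

    qc_dict = qc.to_dict() if isinstance(qc, FitQC) else dict(qc)
    return QReportDoc(
        meta={k: meta[k] for k in sorted(meta)},
        qc=qc_dict,
        global_entries=global_entries,
        profiles=prof_doc,
        flags={"flags": dict(flags.flags), "overall": flags.overall},
        snapshots=list(snapshots or []),
        provenance={"pipeline": PIPELINE_VERSION, "model": model.provenance},
    )


# ---------------------------------------------------------------------------
# snapshots


def render_snapshots(
    t1_like: Volume3D, left: LabelMask, right: LabelMask
) -> dict[str, np.ndarray]:
    """Three orthogonal mid-mask slices per side with the mask outline.

    Slice indices are the (rounded) centroid voxel of each mask; the outline
    is the mask boundary (mask minus its erosion) on the chosen slice,
    painted red over the greyscale structural slice. Returns six RGB arrays
    keyed ``{side}_{sagittal|coronal|axial}``.
    """
    images: dict[str, np.ndarray] = {}
    for mask in (left, right):
        assert_same_grid(t1_like, mask)
        if mask.n_voxels == 0:
            raise ValueError(f"empty {mask.side} mask")
        centroid = np.round(np.argwhere(mask.data > 0).mean(axis=0)).astype(int)
        for axis, plane in enumerate(("sagittal", "coronal", "axial")):
            sl = [slice(None)] * 3
            sl[axis] = centroid[axis]
            anat = np.asarray(t1_like.data[tuple(sl)], dtype=float)
            m = np.asarray(mask.data[tuple(sl)]) > 0
            outline = m & ~ndimage.binary_erosion(m)
            lo, hi = anat.min(), anat.max()
            grey = (anat - lo) / (hi - lo) if hi > lo else np.zeros_like(anat)
            rgb = np.stack([grey] * 3, axis=-1)
            rgb[outline] = (1.0, 0.15, 0.15)
            images[f"{mask.side}_{plane}"] = (rgb * 255).astype(np.uint8)
    return images


def save_snapshots(images: dict[str, np.ndarray], out_dir: str) -> list[str]:
    import os

    from matplotlib.image import imsave

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name in sorted(images):
        p = os.path.join(out_dir, f"snapshot_{name}.png")
        # transpose so the first volume axis runs left-right in the image
        imsave(p, np.rot90(images[name]))
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# HTML view


def _fmt(value: float | None, decimals: int) -> str:
    if value is None:
        return "—"
    return f"{value:.{decimals}f}"


def _profile_figure_png(doc: QReportDoc, side: str, metric: str) -> bytes:
    prof = doc.profiles[side]
    pos = prof["positions"]
    vals = [np.nan if v is None else v for v in prof[metric]]
    band = prof["bands"].get(metric)
    fig, ax = plt.subplots(figsize=(4.2, 2.6), dpi=100)
    if band is not None:
        lo = [np.nan if v is None else v for v in band["lo"]]
        hi = [np.nan if v is None else v for v in band["hi"]]
        ax.fill_between(pos, lo, hi, color="#9cc3e5", alpha=0.5, label="normative ±1.96SD")
        mid = (np.asarray(lo) + np.asarray(hi)) / 2
        ax.plot(pos, mid, ":", color="#2e75b6", lw=1)
    ax.plot(pos, vals, "k.-", lw=1.2, ms=4, label="subject")
    ax.set_xlabel("arc position (0 = posterior, 1 = anterior)")
    ax.set_ylabel("area (mm²)" if metric == "area_mm2" else "qT2 (ms)")
    ax.set_title(f"{side} hippocampus", fontsize=9)
    ax.legend(fontsize=6, loc="best")
    fig.tight_layout()
    buf = io.BytesIO()
    fig.savefig(buf, format="png", metadata={"Software": PIPELINE_VERSION})
    plt.close(fig)
    return buf.getvalue()


def render_html(doc: QReportDoc, snapshot_images: dict[str, np.ndarray] | None, out_path: str) -> None:
    """Render the document to one self-contained HTML file.

    Figures are regenerated deterministically from the document arrays and
    embedded base64; no value is computed at render time.
    """
    esc = _html.escape
    rows = []
    for entry in doc.global_entries:
        label, unit, dec = _METRIC_LABELS[entry["metric"]]
        band = (
            f"[{_fmt(entry['lo'], dec)}–{_fmt(entry['hi'], dec)}]"
            if entry["lo"] is not None
            else "no reference"
        )
        rows.append(
            f"<tr><td>{esc(label)}</td><td>{_fmt(entry['value'], dec)} {unit}</td>"
            f"<td>{band}</td></tr>"
        )

    figure_tags = []
    for side in sorted(doc.profiles):
        for metric in ("area_mm2", "qt2_ms"):
            png = _profile_figure_png(doc, side, metric)
            b64 = base64.b64encode(png).decode("ascii")
            figure_tags.append(f'<img src="data:image/png;base64,{b64}" alt="{side} {metric}"/>')

    snap_tags = []
    if snapshot_images:
        from matplotlib.image import imsave

        for name in sorted(snapshot_images):
            buf = io.BytesIO()
            imsave(buf, np.rot90(snapshot_images[name]), format="png")
            b64 = base64.b64encode(buf.getvalue()).decode("ascii")
            snap_tags.append(
                f'<figure><img src="data:image/png;base64,{b64}" alt="{name}" width="180"/>'
                f"<figcaption>{esc(name)}</figcaption></figure>"
            )

    meta_rows = "".join(
        f"<tr><td>{esc(str(k))}</td><td>{esc(str(v))}</td></tr>" for k, v in doc.meta.items()
    )
    qc_rows = "".join(
        f"<tr><td>{esc(str(k))}</td><td>{esc(str(v))}</td></tr>" for k, v in doc.qc.items()
    )
    flag_rows = "".join(
        f"<tr><td>{esc(k)}</td><td>{esc(v)}</td></tr>" for k, v in doc.flags["flags"].items()
    )

    body = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"/><title>Hippocampal quantitative report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 62em; }}
table {{ border-collapse: collapse; margin-bottom: 1.5em; }}
td, th {{ border: 1px solid #bbb; padding: 0.25em 0.7em; font-size: 90%; }}
h2 {{ border-bottom: 2px solid #2e75b6; }}
figure {{ display: inline-block; margin: 0.3em; }}
.advice {{ background: #fff3cd; padding: 0.6em; border: 1px solid #e0c060; }}
</style></head><body>
<h1>Hippocampal quantitative report</h1>
<h2>Patient</h2><table>{meta_rows}</table>
<h2>Quality control</h2><table>{qc_rows}</table>
<h2>Global analysis</h2>
<table><tr><th>Metric</th><th>Value</th><th>Reference range</th></tr>{''.join(rows)}</table>
<p class="advice">Machine advice (not a diagnosis): overall impression
<b>{esc(doc.flags['overall'])}</b>.</p>
<table><tr><th>Metric</th><th>Flag</th></tr>{flag_rows}</table>
<h2>Segmentation snapshots</h2>{''.join(snap_tags) or '<p>none</p>'}
<h2>Long-axis profiles (posterior → anterior)</h2>{''.join(figure_tags)}
<h2>Provenance</h2><pre>{esc(json.dumps(doc.provenance, indent=1, sort_keys=True))}</pre>
</body></html>
"""
    with open(out_path, "w") as fh:
        fh.write(body)
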