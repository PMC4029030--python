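"""Three-panel alignment pictures.

Each candidate is rendered as three stacked panels — the rearranged
(SV-supporting) alignment on top, the two contiguous alignments below —
with one read-pair per row.  Reads are gray bars with a black cap at the
3'-end; red dashes mark mismatches; light blue marks deletions and, when it
crosses the junction gap, a split-read.  Clipped bases are not drawn and
appear as shortened bars (they still count as mismatches in the score; the
divergence between picture and score is deliberate and documented).

Rendering is manifest-driven: :func:`glyph_manifest` produces the exact
list of drawables and :func:`render_candidate` draws that list, so tests
assert on the manifest rather than on pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import matplotlib

matplotlib.use("Agg", force=False)
from matplotlib import rc_context
from matplotlib.figure import Figure

from .realign import ReadAlignment, TripleAlignment
from .references import ReferenceTriple

__all__ = ["RenderSpec", "Glyph", "glyph_manifest", "render_candidate"]

PANELS = ("sv", "c5", "c3")


@dataclass
class RenderSpec:
    fmt: str = "png"  # png | pdf | svg
    dpi: int = 150
    body_color: str = "0.6"
    cap_color: str = "black"
    mismatch_color: str = "red"
    indel_color: str = "lightblue"
    connector_color: str = "0.75"
    banner: bool = False  # reserved: breakpoint sequence banner
    cap_bp: int = 2  # drawn width of the 3'-end cap, in bp


class Glyph(NamedTuple):
    kind: str  # body | cap | mismatch | gap | split | connector
    panel: str  # sv | c5 | c3
    row: int
    x0: float
    x1: float


def _row_order(triple: TripleAlignment) -> list[str]:
    """Pairs sorted by descending SV-configuration score, ties by name."""
    scores: dict[str, float] = {}
    for a in triple.sv:
        scores[a.read_name] = scores.get(a.read_name, 0.0) + a.score
    return sorted(scores, key=lambda n: (-scores[n], n))


def _three_prime(a: ReadAlignment) -> tuple[float, float]:
    if a.is_reverse:
        return (a.ref_start, a.ref_start + 1)
    return (a.ref_end - 1, a.ref_end)


def _read_glyphs(a: ReadAlignment, panel: str, row: int, junction: Optional[int]) -> list[Glyph]:
    out = [Glyph("body", panel, row, a.ref_start, a.ref_end)]
    runs: list[tuple[int, int]] = []  # deletion runs in ref coords
    prev_kind = None
    for op in a.ops:
        if op.kind == "mismatch":
            out.append(Glyph("mismatch", panel, row, op.ref_pos, op.ref_pos + 1))
        elif op.kind == "deletion":
            if prev_kind == "deletion":
                runs[-1] = (runs[-1][0], op.ref_pos + 1)
            else:
                runs.append((op.ref_pos, op.ref_pos + 1))
        prev_kind = op.kind
    out.extend(Glyph("gap", panel, row, x0, x1) for x0, x1 in runs)
    if panel == "sv" and junction is not None and a.crosses_junction:
        out.append(Glyph("split", panel, row, junction - 1, junction + 1))
    return out


def glyph_manifest(
    triple: TripleAlignment, refs: ReferenceTriple, spec: Optional[RenderSpec] = None
) -> list[Glyph]:
    """The exact list of drawables the renderer will paint.

    Rows are identical across the three panels.  For pairs whose mate
    alignments overlap, a single cap marks the 3'-end of the forward read;
    otherwise each read gets its own cap.
    """
    spec = spec or RenderSpec()
    order = _row_order(triple)
    row_of = {name: i for i, name in enumerate(order)}
    glyphs: list[Glyph] = []
    for panel, alignments in triple.items():
        junction = triple.junction_offset if panel == "sv" else None
        by_name: dict[str, list[ReadAlignment]] = {}
        for a in alignments:
            by_name.setdefault(a.read_name, []).append(a)
        for name, alns in sorted(by_name.items(), key=lambda kv: row_of[kv[0]]):
            row = row_of[name]
            alns = sorted(alns, key=lambda a: a.which_read)
            for a in alns:
                glyphs.extend(_read_glyphs(a, panel, row, junction))
            if len(alns) == 2:
                a1, a2 = alns
                overlap = a1.ref_start < a2.ref_end and a2.ref_start < a1.ref_end
                if overlap:
                    fwd = a1 if not a1.is_reverse else a2
                    glyphs.append(Glyph("cap", panel, row, *_three_prime(fwd)))
                else:
                    glyphs.append(Glyph("cap", panel, row, *_three_prime(a1)))
                    glyphs.append(Glyph("cap", panel, row, *_three_prime(a2)))
                    left, right = sorted(alns, key=lambda a: a.ref_start)
                    if left.ref_end < right.ref_start:
                        glyphs.append(
                            Glyph("connector", panel, row, left.ref_end, right.ref_start)
                        )
            else:
                for a in alns:
                    glyphs.append(Glyph("cap", panel, row, *_three_prime(a)))
    return glyphs


_PANEL_TITLES = {
    "sv": "rearranged (SV) reference",
    "c5": "contiguous reference, 5' side",
    "c3": "contiguous reference, 3' side",
}


def render_candidate(
    triple: TripleAlignment,
    refs: ReferenceTriple,
    spec: Optional[RenderSpec] = None,
    out: str = "candidate.png",
) -> str:
    """Draw the three-panel picture to ``out``.

    Panels are left-aligned on a shared bp scale.  SVG output is
    byte-deterministic for identical inputs.
    """
    spec = spec or RenderSpec()
    if not triple.sv:
        raise ValueError("cannot render an empty TripleAlignment")
    glyphs = glyph_manifest(triple, refs, spec)
    n_rows = max(g.row for g in glyphs) + 1
    max_len = max(len(refs.sv.seq), len(refs.contig5), len(refs.contig3))
    fig = Figure(figsize=(10, 1.0 + 0.14 * n_rows * 3), dpi=spec.dpi)
    axes = fig.subplots(3, 1, sharex=True)
    ax_of = dict(zip(PANELS, axes))
    colors = {
        "body": spec.body_color,
        "cap": spec.cap_color,
        "mismatch": spec.mismatch_color,
        "gap": spec.indel_color,
        "split": spec.indel_color,
    }
    heights = {"body": 0.55, "cap": 0.55, "mismatch": 0.55, "gap": 0.3, "split": 0.55}
    for g in glyphs:
        ax = ax_of[g.panel]
        y = n_rows - 1 - g.row
        if g.kind == "connector":
            ax.plot(
                [g.x0, g.x1], [y, y],
                color=spec.connector_color, linewidth=0.7, zorder=1,
            )
            continue
        h = heights[g.kind]
        width = g.x1 - g.x0
        if g.kind == "cap":
            width = max(width, spec.cap_bp)
        ax.broken_barh(
            [(g.x0, width)], (y - h / 2, h),
            facecolors=colors[g.kind], edgecolors="none",
            zorder={"body": 2, "gap": 3, "split": 3, "mismatch": 4, "cap": 5}[g.kind],
        )
    for panel, ax in ax_of.items():
        ax.set_xlim(0, max_len)
        ax.set_ylim(-1, n_rows)
        ax.set_yticks([])
        ax.set_title(_PANEL_TITLES[panel], fontsize=9, loc="left")
        if panel == "sv":
            ax.axvline(triple.junction_offset, color="white", linewidth=3, zorder=3.5)
            ax.axvline(
                triple.junction_offset, color="0.3", linewidth=0.8,
                linestyle=":", zorder=3.6,
            )
    axes[-1].set_xlabel("position in reference window (bp)")
    fig.suptitle(triple.candidate_id, fontsize=11)
    with rc_context({"svg.hashsalt": "svrescore"}):
        metadata = {"Date": None} if str(out).endswith(".svg") or spec.fmt == "svg" else None
        fig.savefig(str(out), format=spec.fmt, dpi=spec.dpi, metadata=metadata)
    return str(out)
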