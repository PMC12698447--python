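"""GFF3 reading/writing and locus-map rendering.

The dialect: feature types ``V_gene_segment``, ``D_gene_segment``,
``J_gene_segment``, ``C_gene_segment``, ``L_PART1`` (plus ``exon`` children of
C genes); ``functionality``, ``family``, ``anchors``, ``rss``/``rss_3p`` and
``note`` as attributes. Coordinates convert between the package's 0-based
half-open convention and GFF3's 1-based inclusive at this boundary only.
Output is canonical (sorted records, fixed attribute order), so
write -> read -> write is byte-identical.
"""

from __future__ import annotations

import io
from typing import Optional, Union

from .model import GeneSegment, LocusAnnotation, RSSHit

SOURCE = "tcrlocus"

_TYPE_OF_KIND = {
    "V": "V_gene_segment",
    "D": "D_gene_segment",
    "J": "J_gene_segment",
    "C": "C_gene_segment",
    "L-PART1": "L_PART1",
}
_KIND_OF_TYPE = {v: k for k, v in _TYPE_OF_KIND.items()}

_ESCAPE = {"%": "%25", ";": "%3B", "=": "%3D", "&": "%26", ",": "%2C",
           "\t": "%09", "\n": "%0A", "\r": "%0D"}


def escape_attr(value: str) -> str:
    out = value.replace("%", "%25")
    for ch, rep in _ESCAPE.items():
        if ch != "%":
            out = out.replace(ch, rep)
    return out


def unescape_attr(value: str) -> str:
    out = []
    i = 0
    while i < len(value):
        if value[i] == "%" and i + 3 <= len(value):
            try:
                out.append(chr(int(value[i + 1:i + 3], 16)))
                i += 3
                continue
            except ValueError:
                pass
        out.append(value[i])
        i += 1
    return "".join(out)


def _rss_attr(h: RSSHit) -> str:
    return (f"{h.heptamer_start}|{h.spacer_len}|{h.nonamer_start}|{h.strand}|"
            f"{h.mismatches_heptamer}|{h.mismatches_nonamer}")


def _rss_from_attr(s: str) -> RSSHit:
    hept, sp, nona, strand, mmh, mmn = s.split("|")
    return RSSHit(heptamer_start=int(hept), spacer_len=int(sp),
                  nonamer_start=int(nona), strand=strand,
                  mismatches_heptamer=int(mmh), mismatches_nonamer=int(mmn))


def _segment_attributes(seg: GeneSegment, seg_id: str) -> str:
    parts = [f"ID={escape_attr(seg_id)}"]
    if seg.name:
        parts.append(f"Name={escape_attr(seg.name)}")
    parts.append(f"functionality={seg.functionality}")
    if seg.family is not None:
        parts.append(f"family={seg.family}")
    if seg.conserved_positions:
        anchors = ",".join(f"{k}:{v}" for k, v in sorted(seg.conserved_positions.items()))
        parts.append(f"anchors={anchors}")
    if seg.rss is not None:
        parts.append(f"rss={_rss_attr(seg.rss)}")
    if seg.rss_3p is not None:
        parts.append(f"rss_3p={_rss_attr(seg.rss_3p)}")
    if seg.splice_donor is not None:
        parts.append(f"splice_donor={'1' if seg.splice_donor else '0'}")
    if seg.splice_acceptor is not None:
        parts.append(f"splice_acceptor={'1' if seg.splice_acceptor else '0'}")
    if seg.notes:
        parts.append(f"note={escape_attr(seg.notes)}")
    return ";".join(parts)


def write_gff(locus: LocusAnnotation, path: Union[str, "io.TextIOBase"]) -> None:
    """Write a locus as canonical GFF3 (1-based inclusive coordinates)."""
    own = isinstance(path, (str, bytes))
    fh = open(path, "w") if own else path
    try:
        fh.write("##gff-version 3\n")
        fh.write(f"#!scaffold {locus.scaffold}\n")
        fh.write(f"#!locus-label {locus.locus_label}\n")
        fh.write(f"#!orientation {locus.orientation}\n")
        for i, seg in enumerate(locus.sorted_segments(), start=1):
            seg_id = f"{locus.locus_label}.{i:04d}"
            ftype = _TYPE_OF_KIND[seg.kind]
            attrs = _segment_attributes(seg, seg_id)
            fh.write("\t".join([locus.scaffold, SOURCE, ftype,
                                str(seg.start + 1), str(seg.end), ".",
                                seg.strand, ".", attrs]) + "\n")
            if seg.kind == "C":
                n_ex = len(seg.exons)
                for k, (a, b) in enumerate(sorted(seg.exons), start=1):
                    label = k if seg.strand == "+" else n_ex - k + 1
                    ex_attrs = f"ID={seg_id}.EX{label};Parent={seg_id};Name=EX{label}"
                    fh.write("\t".join([locus.scaffold, SOURCE, "exon",
                                        str(a + 1), str(b), ".", seg.strand,
                                        ".", ex_attrs]) + "\n")
    finally:
        if own:
            fh.close()


def _parse_attrs(field: str, lineno: int) -> dict:
    attrs = {}
    for item in field.split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed attribute {item!r} on line {lineno}")
        k, v = item.split("=", 1)
        attrs[k] = unescape_attr(v)
    return attrs


def read_gff(path: Union[str, "io.TextIOBase"]) -> LocusAnnotation:
    """Parse a GFF3 file produced by :func:`write_gff` (inverse on its output).

    Malformed lines raise ValueError naming the line number.
    """
    own = isinstance(path, (str, bytes))
    fh = open(path) if own else path
    scaffold = ""
    label = ""
    orientation = "FWD"
    segments: list[GeneSegment] = []
    pending_exons: dict[str, list[tuple[int, int]]] = {}
    by_id: dict[str, GeneSegment] = {}
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#!scaffold "):
                scaffold = line.split(" ", 1)[1]
                continue
            if line.startswith("#!locus-label "):
                label = line.split(" ", 1)[1]
                continue
            if line.startswith("#!orientation "):
                orientation = line.split(" ", 1)[1]
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"expected 9 tab-separated columns on line {lineno}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attr_field = cols
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError:
                raise ValueError(f"non-integer coordinates on line {lineno}") from None
            if start_i < 0 or end_i <= start_i:
                raise ValueError(f"invalid coordinate range on line {lineno}")
            attrs = _parse_attrs(attr_field, lineno)
            scaffold = scaffold or seqid
            if ftype == "exon":
                parent = attrs.get("Parent", "")
                pending_exons.setdefault(parent, []).append((start_i, end_i))
                continue
            if ftype not in _KIND_OF_TYPE:
                raise ValueError(f"unknown feature type {ftype!r} on line {lineno}")
            seg = GeneSegment(kind=_KIND_OF_TYPE[ftype], start=start_i, end=end_i,
                              strand=strand, locus_label=label,
                              functionality=attrs.get("functionality", "unassigned"),
                              family=int(attrs["family"]) if "family" in attrs else None,
                              name=attrs.get("Name"),
                              notes=attrs.get("note", ""))
            if "anchors" in attrs and attrs["anchors"]:
                seg.conserved_positions = {
                    k: int(v) for k, v in
                    (item.split(":") for item in attrs["anchors"].split(","))
                }
            if "rss" in attrs:
                seg.rss = _rss_from_attr(attrs["rss"])
            if "rss_3p" in attrs:
                seg.rss_3p = _rss_from_attr(attrs["rss_3p"])
            if "splice_donor" in attrs:
                seg.splice_donor = attrs["splice_donor"] == "1"
            if "splice_acceptor" in attrs:
                seg.splice_acceptor = attrs["splice_acceptor"] == "1"
            if "ID" in attrs:
                by_id[attrs["ID"]] = seg
            segments.append(seg)
    finally:
        if own:
            fh.close()
    for parent, exons in pending_exons.items():
        if parent in by_id:
            by_id[parent].exons = sorted(exons)
    locus = LocusAnnotation(scaffold=scaffold, locus_label=label,
                            orientation=orientation, segments=segments)
    locus.segments = locus.sorted_segments()
    return locus


def structurally_equal(a: LocusAnnotation, b: LocusAnnotation) -> bool:
    """Structural equality of two annotations (what GFF round-trips)."""
    def view(loc):
        return [(s.kind, s.start, s.end, s.strand, s.functionality, s.family,
                 s.name, dict(s.conserved_positions), s.rss, s.rss_3p,
                 sorted(s.exons), s.notes) for s in loc.sorted_segments()]

    return (a.scaffold, a.locus_label, a.orientation) == \
        (b.scaffold, b.locus_label, b.orientation) and view(a) == view(b)


_GLYPH = {"V": "V", "D": "D", "J": "J", "C": "C", "L-PART1": "L"}


def render_locus_map(locus: LocusAnnotation, path: Optional[str] = None) -> list[str]:
    """Render a to-scale locus map.

    Always returns a plain-text track (one glyph line per segment, coordinate
    order, orientation arrows); when ``path`` ends in .png/.svg/.pdf a
    matplotlib figure is also written.
    """
    lines = [f"# {locus.locus_label} ({locus.orientation}) on {locus.scaffold} "
             f"span={locus.span[0]}-{locus.span[1]}"]
    for seg in locus.sorted_segments():
        arrow = ">" if seg.strand == "+" else "<"
        name = seg.name or "."
        lines.append(f"{_GLYPH[seg.kind]}{arrow} {seg.start}-{seg.end} {name} "
                     f"[{seg.functionality}]")
    if path and path.rsplit(".", 1)[-1].lower() in ("png", "svg", "pdf"):
        _render_figure(locus, path)
    elif path:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    return lines


def _render_figure(locus: LocusAnnotation, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"V": "#4878d0", "D": "#ee854a", "J": "#6acc64", "C": "#d65f5f",
              "L-PART1": "#956cb4"}
    fig, ax = plt.subplots(figsize=(12, 2.2))
    for seg in locus.sorted_segments():
        y = 0.6 if seg.strand == "+" else 0.2
        ax.broken_barh([(seg.start, seg.end - seg.start)], (y, 0.18),
                       facecolors=colors[seg.kind])
        marker = seg.end if seg.strand == "+" else seg.start
        ax.plot([marker], [y + 0.09], marker=">" if seg.strand == "+" else "<",
                color="black", markersize=3)
    lo, hi = locus.span
    ax.set_xlim(lo - 0.02 * (hi - lo + 1), hi + 0.02 * (hi - lo + 1))
    ax.set_ylim(0, 1)
    ax.set_yticks([0.29, 0.69])
    ax.set_yticklabels(["-", "+"])
    ax.set_title(f"{locus.locus_label} ({locus.orientation})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_fasta(records: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
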