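"""Glossary-coded seizure semiology sequences and group temporal consensus.

Each seizure is an ordered list of timestamped behavioral events drawn from
a published semiology glossary (``STAR`` staring, ``OA`` oral automatisms,
``GTCC`` bilateral tonic-clonic, ...).  The group consensus orders codes by
the median of per-subject *first* onsets, a robust choice at the small group
sizes involved (n <= 8); ties in the median are broken lexicographically so
rendered flowcharts are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import datasets
from .atlas import FormatError

__all__ = [
    "SeizureSequence",
    "GroupSequence",
    "parse_sequences",
    "group_consensus",
    "render_flowchart",
]


@dataclass
class SeizureSequence:
    """One seizure: events sorted by onset, ties keeping file order."""

    subject_id: str
    seizure_id: str
    events: list = field(default_factory=list)  # (code, onset_s[, end_s])


@dataclass
class GroupSequence:
    """Consensus ordering of codes for one epilepsy group."""

    epilepsy_group: str
    motifs: list  # (code, median_onset_s, (min_onset, max_onset), n_subjects)


def parse_sequences(path, glossary: pd.DataFrame | None = None) -> list:
    """Read a semiology event TSV into validated sequences.

    Expects columns ``subject_id, seizure_id, code, onset_s`` (optional
    ``end_s``).  Unknown codes and negative onsets are format errors; within
    a seizure, events are sorted by onset with a stable tie order equal to
    file order.
    """
    if glossary is None:
        glossary = datasets.load_glossary()
    codes = set(glossary["code"])
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "seizure_id": str})
    required = {"subject_id", "seizure_id", "code", "onset_s"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sequence table missing columns: {sorted(missing)}")
    unknown = set(df["code"]) - codes
    if unknown:
        raise FormatError(f"unknown semiology code(s): {sorted(unknown)}")
    if (pd.to_numeric(df["onset_s"]) < 0).any():
        raise FormatError("negative onset_s")
    has_end = "end_s" in df.columns
    if has_end:
        bad = df["end_s"].notna() & (df["end_s"] < df["onset_s"])
        if bad.any():
            raise FormatError("end_s before onset_s")

    out = []
    for (sid, zid), g in df.groupby(["subject_id", "seizure_id"], sort=True):
        g = g.sort_values("onset_s", kind="stable")
        events = []
        for _, r in g.iterrows():
            if has_end and pd.notna(r.get("end_s")):
                events.append((r["code"], float(r["onset_s"]), float(r["end_s"])))
            else:
                events.append((r["code"], float(r["onset_s"])))
        out.append(SeizureSequence(sid, zid, events))
    return out


def group_consensus(sequences: list, group_of: dict, group: str) -> GroupSequence:
    """Median-first-onset consensus ordering for one epilepsy group.

    ``group_of`` maps subject_id to group.  For each code, the first onset
    per subject is collected across that subject's seizures; the motif list
    is ordered by the median of those first onsets (code-lexicographic on
    ties) and carries the observed onset range and subject count.
    """
    seqs = [s for s in sequences if group_of.get(s.subject_id) == group]
    if not seqs:
        raise ValueError(f"no sequences for group {group!r}")
    first: dict = {}  # code -> {subject: first onset}
    for s in seqs:
        for ev in s.events:
            code, onset = ev[0], ev[1]
            per = first.setdefault(code, {})
            if s.subject_id not in per or onset < per[s.subject_id]:
                per[s.subject_id] = onset
    motifs = []
    for code, per in first.items():
        onsets = sorted(per.values())
        motifs.append((
            code,
            float(pd.Series(onsets).median()),
            (min(onsets), max(onsets)),
            len(per),
        ))
    motifs.sort(key=lambda m: (m[1], m[0]))
    return GroupSequence(group, motifs)


def render_flowchart(seq) -> str:
    """Render a sequence as a DOT-compatible directed graph.

    Nodes are codes annotated with onsets; edges follow temporal order (a
    linear chain: n events give n - 1 edges).  Works on a single seizure or
    a group consensus.
    """
    if isinstance(seq, SeizureSequence):
        title = f"{seq.subject_id}_{seq.seizure_id}"
        nodes = [(ev[0], ev[1]) for ev in seq.events]
    elif isinstance(seq, GroupSequence):
        title = seq.epilepsy_group
        nodes = [(code, median) for code, median, _rng, _n in seq.motifs]
    else:
        raise TypeError(f"cannot render {type(seq).__name__}")
    if not nodes:
        raise ValueError("empty sequence")
    lines = [f'digraph "{title}" {{']
    for code, onset in nodes:
        lines.append(f'  "{code}" [label="{code}\\n{onset:g} s"];')
    for (a, _), (b, _) in zip(nodes, nodes[1:]):
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines)
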