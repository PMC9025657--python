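"""Loaders for the packaged fixture tables.

The package ships, as versioned TSV files, the per-subject clinical tables of
the study it implements (demographics, seizure counts and radiotracer
injection times, the interictal and ictal perfusion-index tables with their
per-subject thresholds) plus the seizure-semiology glossary and a *synthetic*
set of semiology sequences consistent with the narrative onset windows.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import atlas

__all__ = [
    "fixture_path",
    "load_atlas",
    "load_subjects",
    "load_perfusion",
    "load_thresholds",
    "load_glossary",
    "load_sequences_path",
]

_FILES = {
    "atlas": "atlas_regions.tsv",
    "subjects": "subjects.tsv",
    "pi_interictal": "pi_interictal.tsv",
    "pi_ictal": "pi_ictal.tsv",
    "thresholds": "pi_thresholds.tsv",
    "glossary": "semiology_glossary.tsv",
    "sequences": "semiology_sequences_synthetic.tsv",
}


def fixture_path(name: str):
    """Filesystem path of a packaged fixture, addressable by short name."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; options: {sorted(_FILES)}")
    return resources.files("spectperf.data").joinpath(_FILES[name])


def load_atlas() -> pd.DataFrame:
    """Default 74-region bilateral atlas lookup (37 name codes x 2 sides)."""
    return atlas.read_region_table(fixture_path("atlas"))


def load_subjects() -> pd.DataFrame:
    """Roster of the 15 study subjects with clinical covariates."""
    return atlas.read_subject_table(fixture_path("subjects"))


def load_perfusion(state: str) -> pd.DataFrame:
    """Packaged perfusion-index table for ``ictal`` or ``interictal``."""
    if state not in atlas.STATES:
        raise ValueError(f"state must be one of {atlas.STATES}")
    return atlas.read_perfusion_table(fixture_path(f"pi_{state}"))


def load_thresholds() -> pd.DataFrame:
    """Per-subject perfusion-index cut-offs as published (both states)."""
    df = pd.read_csv(fixture_path("thresholds"), sep="\t",
                     dtype={"subject_id": str})
    return df


def load_glossary() -> pd.DataFrame:
    """Seizure-semiology code glossary used by the sequence encoder."""
    df = pd.read_csv(fixture_path("glossary"), sep="\t")
    if df["code"].duplicated().any():
        raise atlas.FormatError("duplicate glossary code")
    return df


def load_sequences_path():
    """Path to the synthetic semiology sequence fixture (TSV)."""
    return fixture_path("sequences")
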