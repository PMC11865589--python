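"""Shared paths and loaders for the numbered analysis scripts."""

from pathlib import Path

from syn4d import formats_io as fio

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
FIXTURE = RESULTS / "fixture"


def load_fixture():
    """Load the simulated input bundle written by 01_simulate_data.py."""
    if not FIXTURE.is_dir():
        raise SystemExit("run analysis/01_simulate_data.py first")
    genome = fio.read_fasta(str(FIXTURE / "genome.fa"))
    transcripts = fio.read_transcripts(str(FIXTURE / "annotation.gtf"))
    alignment = fio.read_alignment(str(FIXTURE / "alignment.tsv"))
    scores = fio.read_score_track(str(FIXTURE / "scores.bedgraph"))
    variants = fio.read_variants(str(FIXTURE / "variants.tsv"))
    return genome, transcripts, alignment, scores, variants


def load_tau() -> float:
    import json

    with open(FIXTURE / "manifest.json") as fh:
        return float(json.load(fh)["tau"])
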