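"""Shared configuration for the numbered analysis drivers."""

from pathlib import Path

from fundingaudit.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
FIXTURE = ROOT / "results" / "fixture"
AUDIT = ROOT / "results" / "audit"


def audit_config(stages: tuple[str, ...]) -> PipelineConfig:
    if not (FIXTURE / "corpus.jsonl").exists():
        raise SystemExit("run 01_simulate_corpus.py first")
    return PipelineConfig(
        corpus_path=str(FIXTURE / "corpus.jsonl"),
        disclosure_path=str(FIXTURE / "disclosure.csv"),
        survey_path=str(FIXTURE / "survey.csv"),
        out_dir=str(AUDIT),
        seed=640531,
        # the fixture's abstracts carry six planted topics; 600 sweeps keeps
        # the fit inside a couple of minutes on one core
        topic_k=6, topic_iterations=600, topic_burn_in=200,
        stages=stages,
    )
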