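"""End-to-end orchestration: counts -> DE -> triplets -> interaction calls ->
optional enrichment and ligand–receptor reports, all written to an output
directory together with a machine-readable run manifest."""

from __future__ import annotations

import json
import logging
import sys
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__, annotation, expression, interaction, io
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


@contextmanager
def _stage(name: str):
    start = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done (%.2fs)", name, time.perf_counter() - start)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        force=True,
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full factorial analysis and write all result tables.

    Returns a mapping from artifact name to the written path. Outputs are
    deterministic: identical config and inputs yield byte-identical tables.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    with _stage("load"):
        matrix = io.read_count_matrix(config.counts, config.metadata)
        matrix.require_conditions(("control", "A", "B", "AB"))

    with _stage("normalize"):
        factors = expression.size_factors(matrix, method=config.normalization)

    with _stage("differential-expression"):
        de = expression.de_all_contrasts(
            matrix,
            factors,
            fc_threshold=config.fc_threshold,
            alpha=config.de_alpha,
            pseudocount=config.pseudocount,
        )
        for contrast, sub in de.groupby("contrast"):
            path = out_dir / f"de_{contrast}.tsv"
            io.write_table(sub, path)
            written[f"de_{contrast}"] = path

    with _stage("effect-estimation"):
        effects = expression.estimate_effects(
            matrix, factors, pseudocount=config.pseudocount
        )
        triplets = interaction.build_triplets(effects)
        path = out_dir / "effect_triplets.tsv"
        io.write_table(triplets, path)
        written["effect_triplets"] = path

    with _stage("classification"):
        calls, summary = interaction.classify_all(
            triplets,
            de,
            alpha=config.test_alpha,
            eligibility=config.eligibility,
            adjust_tests=config.adjust_interaction_tests,
        )
        path = out_dir / "interaction_calls.tsv"
        io.write_table(calls, path)
        written["interaction_calls"] = path
        path = out_dir / "summary.tsv"
        summary.reset_index().to_csv(path, sep="\t", index=False)
        written["summary"] = path

    asg = calls[calls["category"].isin(interaction.ASG_CATEGORIES)]

    if config.gene_sets is not None:
        with _stage("enrichment"):
            sets = annotation.read_gmt(config.gene_sets)
            collection = annotation.GeneSetCollection(sets, matrix.gene_ids)
            ora = annotation.ora_test(asg["gene_id"], collection, strict=False)
            path = out_dir / "ora.tsv"
            io.write_table(ora, path, sort_by=None)
            written["ora"] = path

    if config.pairs is not None:
        with _stage("ligand-receptor"):
            pairs = io.read_pairs(config.pairs)
            report = annotation.pair_coregulation(calls, pairs)
            path = out_dir / "pairs.tsv"
            io.write_table(report, path, sort_by="pair")
            written["pairs"] = path

    with _stage("manifest"):
        manifest = {
            "config": config.to_dict(),
            "versions": {
                "cytosynergy": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "statsmodels": statsmodels.__version__,
            },
            "n_genes": int(matrix.counts.shape[0]),
            "n_samples": int(matrix.counts.shape[1]),
            "n_eligible": int(len(calls)),
            "n_asg": int(len(asg)),
            "outputs": {k: str(v) for k, v in sorted(written.items())},
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
        written["manifest"] = path

    return written
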