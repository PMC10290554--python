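"""End-to-end pipeline driver: FASTA in, motif reports out."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np

from . import seq_io
from .estimators import MotifDiscovery

logger = logging.getLogger("sparsemotif")

#: CPU-friendly defaults for interactive runs.
DESK_PROFILE = dict(M=12, K=8, filter_height=6, epochs=10)
#: The full-scale configuration.
PAPER_PROFILE = dict(M=50, K=24, filter_height=12, epochs=20)


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the reference settings."""

    M: int = 12
    filter_len: int = 8
    K: int = 8
    filter_height: int = 6
    alpha: int = 32
    beta: float = 100.0
    q: int = 3
    K1: int = 6
    K2: int = 3
    batch_size: int = 6
    epochs: int = 10
    learning_rate: float = 1e-3
    seed: int = 0
    mode: str = "classical"
    test_fraction: float = 0.15
    scan_pvalue: float = 1e-3
    significance_pvalue: float = 1e-6
    top_j: int = 1000
    outer_rounds: int = 8
    admm_iters: int = 10

    def apply_profile(self, profile: str) -> "RunConfig":
        values = {"desk": DESK_PROFILE, "paper": PAPER_PROFILE}[profile]
        return dataclasses.replace(self, **values)


def discover(fasta_path, out_dir, config: RunConfig | None = None) -> Path:
    """Run the full discovery pipeline and write the result files.

    Writes ``motifs.meme``, ``report.tsv``, ``run.json`` and ``run.log``
    into ``out_dir``; returns the output directory.  Aborts with the failing
    stage named in the exception.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        stage = "read_fasta"
        records = seq_io.read_fasta(fasta_path)
        if len(records) < 20:
            raise ValueError("need at least 20 sequences")
        logger.info("read %d records from %s", len(records), fasta_path)

        stage = "discover"
        md = MotifDiscovery(
            M=config.M, filter_len=config.filter_len, K=config.K,
            filter_height=config.filter_height, alpha=config.alpha,
            beta=config.beta, q=config.q, mode=config.mode,
            top_j=config.top_j, test_fraction=config.test_fraction,
            scan_pvalue=config.scan_pvalue,
            significance_pvalue=config.significance_pvalue,
            outer_rounds=config.outer_rounds, admm_iters=config.admm_iters,
            epochs=config.epochs, random_state=config.seed)
        md.fit(records)
        logger.info("%d motifs reported, %d significant",
                    len(md.motifs_), len(md.significant_motifs_()))

        stage = "write_outputs"
        md.to_meme(out / "motifs.meme")
        md.report_.to_csv(out / "report.tsv", sep="\t", index=False)
        manifest = dataclasses.asdict(config)
        manifest["n_records"] = len(records)
        manifest["numpy_version"] = np.__version__
        manifest["python_version"] = platform.python_version()
        with open(out / "run.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def report(out_dir) -> str:
    """Human-readable per-motif summary of a completed run."""
    out = Path(out_dir)
    tsv = out / "report.tsv"
    if not tsv.exists():
        raise FileNotFoundError(f"no report.tsv in {out}")
    import pandas as pd

    df = pd.read_csv(tsv, sep="\t")
    lines = []
    sig = df[df["significant"]] if "significant" in df else df
    if len(df) == 0 or len(sig) == 0:
        lines.append("no significant motifs")
    for _, row in df.iterrows():
        lines.append(
            f"{row['motif']}: configuration ({row['configuration']}) "
            f"width {row['width']} instances {row['n_instances']} "
            f"odds ratio {row['odds_ratio']:.3f} "
            f"p-value {row['p_value']:.3g}"
            + ("  *" if row.get("significant", False) else ""))
    return "\n".join(lines)
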