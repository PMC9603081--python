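"""End-to-end driver: calibrate -> select -> enrich -> similarity -> report.

A run takes promoters (FASTA, or genome FASTA + TSS table), a motif
library and a DEG table, runs the enrichment for one or both directions,
computes the similarity matrix over each direction's significant motifs,
and writes a manifest recording the tool version, input digests and every
parameter so the run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .calibration import err_grid
from .deg_selection import build_gene_groups, read_deg_table
from .enrichment import enrich_collection, results_table
from .motifs import parse_motif_library, pcm_to_pwm
from .promoters import PromoterSet, extract_promoters, read_fasta, read_tss_table
from .similarity import similarity_matrix, write_similarity_tsv

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_promoters", "PIPELINE_DEFAULTS"]

PIPELINE_DEFAULTS = {
    "direction": "up,down",
    "p_max": 0.1,
    "min_fold": 2.0,
    "fold_low": 0.80,
    "fold_high": 1.25,
    "err_max": 5e-4,
    "err_min": 1e-4,
    "levels": 30,
    "resamples": 1000,
    "seed": 1,
    "frequency": "promoter",
    "both_strands": True,
    "motif_format": "hocomoco_pcm",
    "report_threshold": 0.05,
    "similarity_permutations": 1000,
    "upstream": 2000,
    "downstream": 1,
}


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def load_promoters(config: dict) -> PromoterSet:
    """Promoters from ``promoters`` FASTA, or ``genome`` + ``tss_table``."""
    if "promoters" in config:
        return PromoterSet.from_fasta(config["promoters"])
    if "genome" in config and "tss_table" in config:
        genome = dict(read_fasta(config["genome"]))
        tss = read_tss_table(config["tss_table"])
        return extract_promoters(
            genome,
            tss,
            upstream=int(config.get("upstream", PIPELINE_DEFAULTS["upstream"])),
            downstream=int(config.get("downstream", PIPELINE_DEFAULTS["downstream"])),
            one_based=bool(config.get("one_based_tss", False)),
        )
    raise ValueError("config must provide 'promoters' or both 'genome' and 'tss_table'")


def run_pipeline(config: dict, outdir) -> Path:
    """Run the full analysis described by a flat config mapping.

    Required keys: promoter input (see :func:`load_promoters`), ``motifs``
    and ``deg_table``.  Everything else falls back to
    :data:`PIPELINE_DEFAULTS`.  Writes, per direction, a full and a
    significant-only ranked motif table, a similarity matrix over the
    significant motifs, and one ``manifest.json``.
    """
    cfg = {**PIPELINE_DEFAULTS, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()

    stage = "load promoters"
    try:
        promoters = load_promoters(cfg)
        stage = "parse motif library"
        pcms = parse_motif_library(cfg["motifs"], format=cfg["motif_format"])
        if cfg.get("exclude_motifs"):
            excluded = {
                line.strip()
                for line in Path(cfg["exclude_motifs"]).read_text().splitlines()
                if line.strip()
            }
            pcms = [m for m in pcms if m.motif_id not in excluded]
        pwms = [pcm_to_pwm(m) for m in pcms]
        stage = "read DEG table"
        records = read_deg_table(cfg["deg_table"])
        stage = "select gene groups"
        groups = build_gene_groups(
            records,
            p_max=float(cfg["p_max"]),
            min_fold=float(cfg["min_fold"]),
            fold_low=float(cfg["fold_low"]),
            fold_high=float(cfg["fold_high"]),
            universe=promoters.gene_ids,
        )
        errs = err_grid(float(cfg["err_max"]), float(cfg["err_min"]), int(cfg["levels"]))
        directions = [d.strip() for d in str(cfg["direction"]).split(",") if d.strip()]
        outputs: list[str] = []
        for direction in directions:
            stage = f"enrichment ({direction})"
            foreground = sorted(groups.foreground(direction))
            if not foreground:
                logger.warning("direction %s: empty foreground, skipped", direction)
                continue
            logger.info(
                "direction %s: %d foreground genes, %d pool genes, %d motifs",
                direction,
                len(foreground),
                len(groups.background_pool),
                len(pwms),
            )
            results = enrich_collection(
                pwms,
                foreground,
                sorted(groups.background_pool),
                promoters,
                errs=errs,
                n_resamples=int(cfg["resamples"]),
                seed=int(cfg["seed"]),
                frequency=str(cfg["frequency"]),
                both_strands=bool(cfg["both_strands"]),
            )
            full_path = outdir / f"enrichment_{direction}_full.tsv"
            results_table(results, report_threshold=None).to_csv(
                full_path, sep="\t", index=False
            )
            sig_path = outdir / f"enrichment_{direction}_significant.tsv"
            sig = results_table(results, report_threshold=float(cfg["report_threshold"]))
            sig.to_csv(sig_path, sep="\t", index=False)
            outputs += [full_path.name, sig_path.name]
            stage = f"similarity ({direction})"
            significant_ids = set(sig["motif_id"]) if len(sig) else set()
            sig_pwms = [p for p in pwms if p.motif_id in significant_ids]
            if len(sig_pwms) >= 2:
                entries = similarity_matrix(
                    sig_pwms,
                    n_perm=int(cfg["similarity_permutations"]),
                    seed=int(cfg["seed"]),
                )
                sim_path = outdir / f"similarity_{direction}.tsv"
                write_similarity_tsv(sig_pwms, entries, sim_path)
                outputs.append(sim_path.name)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    input_keys = ("promoters", "genome", "tss_table", "motifs", "deg_table", "exclude_motifs")
    manifest = {
        "tool": "esdeg",
        "version": __version__,
        "started_utc": started,
        "finished_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": {k: {"path": str(cfg[k]), "sha256": _sha256(cfg[k])} for k in input_keys if cfg.get(k)},
        "parameters": {
            k: cfg[k] for k in sorted(PIPELINE_DEFAULTS) if k in cfg
        },
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2)
    return outdir
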