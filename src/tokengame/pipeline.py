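"""End-to-end analysis pipeline: explore -> fit -> null-compare -> influence -> network.

One call runs the whole workflow on a game and writes every output table
plus a manifest recording the seed and replicate budgets, so a run is fully
reproducible from its output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

from .explore import pair_table, proportions_per_round
from .game import GameData, write_game
from .influence import influence_metrics, influence_report
from .nullcomp import compare, null_reference
from .regression import VARIANTS, fit_trajectory
from .rng import RngSpec
from .viz import build_network, export_graph, layout_positions

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("tokengame")


@dataclass(frozen=True)
class RunConfig:
    """Knobs for one pipeline run.

    ``null_replicates``/``influence_replicates`` default to the full 10,000
    budget; ``fast`` drops both to 1,000 (exploration/CI scale — scores are
    noisier but the workflow is identical).
    """

    seed: int
    out_dir: str
    variant: str = "additive"
    null_replicates: int = 10_000
    influence_replicates: int = 10_000
    level: float = 0.95
    fast: bool = False

    def budgets(self) -> tuple[int, int]:
        if self.fast:
            return min(self.null_replicates, 1000), min(self.influence_replicates, 1000)
        return self.null_replicates, self.influence_replicates


def run_pipeline(game: GameData, config: RunConfig) -> dict[str, Path]:
    """Run every analysis stage on ``game``; returns the written file paths."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = RngSpec(config.seed)
    K, N = config.budgets()
    paths: dict[str, Path] = {}

    stage = "input"
    try:
        write_game(game, out / "game")
        paths["game"] = out / "game"

        stage = "explore"
        log.info("explore: proportions and pair table")
        proportions_per_round(game).to_csv(out / "proportions.csv", index=False)
        pair_table(game, game.n_rounds).to_csv(out / "pairs.csv", index=False)
        paths["proportions"] = out / "proportions.csv"
        paths["pairs"] = out / "pairs.csv"

        stage = "fit"
        log.info("fit: coefficient trajectories for all variants")
        frames = []
        for variant in VARIANTS:
            frame = fit_trajectory(game, variant).to_frame()
            frame.insert(1, "model", variant)
            frames.append(frame)
        import pandas as pd
        pd.concat(frames).to_csv(out / "fits.csv", index=False)
        paths["fits"] = out / "fits.csv"

        stage = "null-compare"
        log.info("null-compare: %d null replicates", K)
        dist = null_reference(game.config, config.variant,
                              range(1, game.n_rounds + 1), K, rng)
        dist.save_csv(out / "null_draws.csv")
        report = compare(game, dist, level=config.level)
        report.save_csv(out / "null_comparison.csv")
        paths["null_draws"] = out / "null_draws.csv"
        paths["null_comparison"] = out / "null_comparison.csv"

        stage = "influence"
        log.info("influence: %d replicates per player", N)
        table = influence_metrics(game, rng, n_replicates=N, variant=config.variant)
        table.save_csv(out / "influence.csv")
        (out / "influence.txt").write_text(influence_report(table))
        paths["influence"] = out / "influence.csv"

        stage = "network"
        log.info("network: build, lay out, export")
        graph = build_network(game, table)
        pos = layout_positions(graph, seed=config.seed)
        export_graph(graph, pos, out / "network.graphml")
        paths["network"] = out / "network.graphml"
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "null_replicates_used": K,
        "influence_replicates_used": N,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = out / "manifest.json"
    log.info("pipeline done in %.1fs", manifest["elapsed_seconds"])
    return paths
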