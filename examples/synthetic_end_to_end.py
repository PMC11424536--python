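"""Full pipeline on a synthetic quarter with one injected signal.

Generates FAERS-style quarterly files (with duplicate case versions and
raw drug-name variants), injects a 10x relative-risk signal on the pair
(sulfasalazine, Stevens-Johnson syndrome), then runs ingest ->
deduplication -> name standardization -> disproportionality and prints
the top-ranked positive signals.
"""

import tempfile
from pathlib import Path

import pandas as pd

from pvsignal import (
    GeneratorConfig,
    PipelineConfig,
    SignalSpec,
    generate_dataset,
    run_pipeline,
)

cfg = GeneratorConfig(n_reports=5000, duplicate_fraction=0.15, seed=1)

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_dataset(cfg, [SignalSpec(drug=0, event=0, rr=10.0)], tmp)
    out = Path(tmp) / "out"
    manifest = run_pipeline(PipelineConfig(
        input_dir=tmp,
        drug="sulfasalazine",
        dictionary_path=bundle["dictionary"],
        meddra_path=bundle["meddra"],
        out_dir=out,
        log_level="WARNING",
    ))
    counts = manifest["counts"]
    print(f"{counts['raw_reports']} raw report versions "
          f"-> {counts['deduplicated_reports']} cases after deduplication "
          f"-> {counts['target_ps_reports']} with the target drug as "
          f"Primary Suspect")
    print(f"{counts['pts_analyzed']} PTs analyzed, "
          f"{counts['pts_flagged']} flagged positive by all four algorithms\n")

    top = pd.read_csv(out / "topk.csv")
    cols = ["event", "soc", "a", "ror", "ror_ci95_low", "ic025", "ebgm05"]
    print(top[cols].head(5).to_string(index=False))
    print()
    print("The injected pair ranks first: its ROR CI lower bound, IC025 and "
          "EBGM05 all clear the positive-signal thresholds, while background "
          "pairs (drawn independently) do not.")
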