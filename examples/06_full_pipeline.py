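"""Run the whole pipeline on synthetic inputs with one config object.

Generates the four input tables, writes them to disk, re-reads them, and
executes build -> embed -> metrics -> null ensembles -> z-scores ->
expression correlation -> gene-set analysis at both the gene and operon
level.  Equivalent CLI: `wireconomy run --config cfg.yaml`.
"""

import json
import tempfile
from pathlib import Path

from wireconomy import RunConfig, run_pipeline

outdir = Path(tempfile.mkdtemp(prefix="wireconomy_"))
config = RunConfig(
    output_dir=str(outdir),
    seed=11,
    level="both",
    synthetic={
        "n_genes": 150,
        "n_regulators": 15,
        "out_degree_law": "fixed",
        "out_degree_param": 8,
        "operon_size_p": 0.5,
        "n_samples": 6,
    },
    n_replicates=50,
)

manifest = run_pipeline(config)
print(f"status: {manifest['status']}  (outputs in {outdir})")
for level, entry in manifest["levels"].items():
    print(f"[{level}] TRN {entry['trn_nodes']} nodes / "
          f"{entry['trn_edges']} edges; CRN {entry['crn_edges']} edges")
    wl_z = {
        r["method"]: round(r["z"], 2)
        for r in entry["zscores"]
        if r["metric_name"] == "total_wiring_length"
    }
    print(f"[{level}] wiring-length z by null model: {json.dumps(wl_z)}")
# Operon-level counts never exceed gene-level counts; with the default
# locality kappa (0.2) every null model flags sub-random wiring.
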