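"""Run the whole pipeline (QC -> ROH -> inbreeding -> islands -> LD) on a
PLINK fixture written to disk, the way the CLI would.

Equivalent shell usage:
    rohscan simulate --config sim.yaml --out data
    rohscan run --geno data --out results/run
"""

import tempfile
from pathlib import Path

from rohscan import SimConfig, simulate_population, write_fixture
from rohscan.pipeline import RunConfig, run_pipeline

cfg = SimConfig(n_chromosomes=6, snps_per_chromosome=800, n_individuals=60,
                target_f=0.08, seed=23)
gm, truth = simulate_population(cfg)

with tempfile.TemporaryDirectory() as td:
    prefix = Path(td) / "pigs"
    paths = write_fixture(gm, truth, prefix)
    report = run_pipeline(str(prefix), RunConfig(), out_prefix=str(Path(td) / "out"),
                          input_paths=[paths["ped"], paths["map"]])
    print("QC:")
    print(report.qc_report.to_frame().to_string(index=False))
    print("\nROH length classes:")
    print(report.table1.to_string(index=False))
    print("\nInbreeding coefficient summary:")
    print(report.inbreeding_summary.round(4).to_string(index=False))
    print(f"\n{len(report.islands)} ROH islands at incidence >= "
          f"{report.island_threshold:.3f}")
    outputs = sorted(p.name for p in Path(td).glob("out.*"))
    print("\nstage outputs written:", ", ".join(outputs))
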