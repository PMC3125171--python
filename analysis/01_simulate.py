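"""Generate the synthetic four-genotype microarray experiment.

Plants known FPR1/FMR1/SNP regulatory architectures into a 1000-gene,
4-replicate two-color design against a common reference and writes the
probe-level table plus the ground truth under results/synthetic/.
"""

import sys
from pathlib import Path

from matreg import SimulationDesign, simulate_expression
from matreg.io import write_tsv

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = SimulationDesign(n_genes=1000, seed=seed, n_matplus_specific=13,
                              n_matminus_specific=6)
    probes, truth = simulate_expression(design)
    write_tsv(probes, OUT / "probes.tsv")
    write_tsv(truth, OUT / "truth.tsv")
    planted = truth[truth.planted_class != "none"]
    print(f"simulated {design.n_genes} genes x {4 * design.n_replicates} arrays "
          f"({len(probes)} spots), seed {seed}")
    print(f"planted classes: {planted.planted_class.value_counts().sort_index().to_dict()}")
    print(f"mating-type-specific genes: 13 mat+, 6 mat-; "
          f"non-expressed: {(truth.expressed_in == '.').sum()}")
    print(f"wrote {OUT / 'probes.tsv'} and {OUT / 'truth.tsv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
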