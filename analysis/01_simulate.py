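"""Generate the reference synthetic bundle and write it to scratch/data/.

The bundle provides every input the pipeline needs — interactome,
expression matrix, disease gene sets, GO annotations, GWAS p-values —
together with the ground truth of what was planted, so the downstream
scripts can report recovery rather than just description.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA_DIR, SEED, reference_bundle

from tissuemod.synthetic import write_bundle


def main() -> None:
    bundle = reference_bundle()
    paths = write_bundle(bundle, DATA_DIR)
    g = bundle.interactome
    print(f"seed: {SEED}")
    print(f"interactome: {g.number_of_nodes()} genes, {g.number_of_edges()} interactions")
    print(f"tissues: {bundle.config.n_tissues}, target expressed fraction "
          f"{bundle.config.expressed_fraction:.2f}")
    print(f"diseases: {len(bundle.disease_sets)} "
          f"({len(bundle.truth.true_links)} with planted tissue modules)")
    for d, t in sorted(bundle.truth.true_links):
        print(f"  planted: {d} -> {t} (module of {len(bundle.truth.modules[d])} genes)")
    print(f"wrote {len(paths)} files to {DATA_DIR}")


if __name__ == "__main__":
    main()
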