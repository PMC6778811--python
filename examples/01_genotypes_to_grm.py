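"""From raw SNP calls to a genomic relationship matrix.

Simulates a small inbred diversity panel, writes it in both supported
on-disk formats (PLINK 1 binary and CSV), reads it back, applies the
call-rate/MAF quality filters, mean-imputes the remaining missing calls and
builds the VanRaden relationship matrix G = W_sc W_sc' / p.
"""

import tempfile
from pathlib import Path

import numpy as np

from longrr.genotypes import compute_grm, impute_mean, qc_filter, read_genotypes, write_plink
from longrr.simulate import SimulationConfig, simulate_markers

cfg = SimulationConfig(n_accessions=120, n_markers=1500, missing_rate=0.04, seed=1)
markers = simulate_markers(cfg)
print(f"simulated panel: {markers.n_accessions} accessions x {markers.n_markers} SNPs, "
      f"{np.isnan(markers.dosages).mean():.1%} missing calls")

with tempfile.TemporaryDirectory() as tmp:
    write_plink(markers, Path(tmp) / "panel")
    markers.to_frame().to_csv(Path(tmp) / "panel.csv", na_rep="NA")
    from_bed = read_genotypes(Path(tmp) / "panel.bed", "plink-bed")
    from_csv = read_genotypes(Path(tmp) / "panel.csv", "csv")
    assert np.array_equal(from_bed.dosages, from_csv.dosages, equal_nan=True)
    print("PLINK and CSV round-trips agree")

kept = qc_filter(markers, min_call_rate=0.95, min_maf=0.05)
print(f"QC (call rate > 0.95, MAF > 0.05): {markers.n_markers} -> {kept.n_markers} SNPs")

grm = compute_grm(impute_mean(kept))
off = grm.G[np.triu_indices(grm.G.shape[0], 1)]
print(f"GRM: mean diagonal {np.diag(grm.G).mean():.3f} (centering/scaling check, ~1), "
      f"off-diagonal range [{off.min():.2f}, {off.max():.2f}]")
print("large positive off-diagonals are within-subpopulation pairs; the spread is")
print("what lets genomic prediction transfer information between related lines")
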