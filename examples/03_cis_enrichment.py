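"""Cis-element enrichment of a gene list against a resampled background.

Implants a cis motif into query promoters at five times the background
rate and shows the Z score and p-value the enrichment test reports.
"""

from earminer import CisMotif, cis_enrichment, simulate_promoters

promoters, truth = simulate_promoters(
    n_query=30, n_background=270, length=1000,
    rate_query=5.0, rate_background=1.0, motif="TGACGTCA", seed=5,
)
query = [p.id for p in promoters if p.id.startswith("q")]
motifs = [CisMotif("G-box-like", "TGACGTCA"), CisMotif("TATA", "TATAAA")]

for res in cis_enrichment(query, promoters, motifs, n_random=500, seed=2):
    print(f"{res.motif:12s} observed={res.x_bar:5.0f} mu={res.mu:6.1f} "
          f"sigma={res.sigma:5.1f} Z={res.z:7.2f} z_raw={res.z_raw:5.2f} "
          f"p={res.p:.3g}")

print("\nThe implanted motif shows a large positive z_raw and a tiny p; the "
      "un-implanted TATA control sits near its background mean.  Z is the "
      "conventionally printed statistic (sigma/sqrt(n) denominator); the p-value is "
      "computed on the calibrated sigma scale.")
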