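"""Analytic power calculations used to size the designs.

Two-sample mode solves for the minimum detectable group mean under a
noncentral-t model with Welch-Satterthwaite degrees of freedom; correlation
mode uses a bias-corrected Fisher z approximation.
"""

from strokemap import PowerSpec, min_detectable_correlation, min_detectable_mean

print("behaviour design: 15 vs 15, control 20% +/- 10%, alpha 0.05, power 0.8")
res = min_detectable_mean(PowerSpec(n1=15, n2=15, mean0=20.0, sd0=10.0, sd1=10.0))
print(f"  minimum detectable lesion-group mean: {res.mean1:.1f}% "
      f"(~{round(res.mean1)}%)\n")

print("morphometry design: 30 lesioned vs 10 sham, sham mean J = 1.0")
for sd1 in (0.05, 0.20):
    res = min_detectable_mean(
        PowerSpec(n1=30, n2=10, mean0=1.0, sd0=0.05, sd1=sd1))
    print(f"  lesion SD {sd1:.2f}: minimum detectable mean J = "
          f"{res.mean1:.3f} (log {res.log_mean1:.3f}, df = {res.df:.1f})")

print("\ncorrelation design: one group of n = 30")
r = min_detectable_correlation(30, alpha=0.05, power=0.8)
print(f"  minimum detectable correlation: {r:.3f}")
print(f"  plain Fisher z (no bias correction): "
      f"{min_detectable_correlation(30, method='fisher'):.3f}")
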