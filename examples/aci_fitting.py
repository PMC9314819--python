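"""FvCB A-Ci curve generation and fitting.

Simulates an assimilation-vs-intercellular-CO2 response with known
Rubisco and electron-transport capacities, fits the two-limitation FvCB
model, and labels each point's limiting process.
"""

import leafgas as lg

df = lg.generate_aci_curve(v_cmax=100.0, j_max=150.0, r_d=1.5, noise_sd=0.3, seed=2)
fit = lg.fit_aci(df["Ci"], df["An"], gamma_star=40.0)

print(f"fitted Vcmax = {fit.v_cmax:.1f} (true 100), J = {fit.j_max:.1f} (true 150), "
      f"Rd = {fit.r_d:.2f} (true 1.5)")
print(f"A_max (at Ci = 1500)   = {fit.a_max:.1f} umol m-2 s-1")
print(f"A at compensation point = {fit.predict(fit.gamma_star):.2f} (= -Rd)")
print("per-point limitation:")
for ci, an, lim in zip(df["Ci"], df["An"], fit.limitation):
    print(f"  Ci {ci:6.0f}  An {an:6.2f}  {lim}")
print("Low-Ci points are Rubisco-limited, high-Ci points are limited by RuBP")
print("regeneration; the transition Ci falls where the two rates cross.")
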