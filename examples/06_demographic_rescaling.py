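"""Rescaling coalescent-unit demographic estimates to absolute units.

Diffusion-based SFS fits report sizes in units of a reference population
size N_ref and times in units of 2 N_ref generations. Given the fitted
population-scaled mutation parameter theta, a per-generation mutation rate,
and the callable sequence length, N_ref = theta / (4 mu L) converts
everything to individuals and generations.
"""

from radancestry import DemographicEstimate, rescale_demography, total_bottleneck_time

est = DemographicEstimate(
    theta=68.40,        # fitted population-scaled mutation parameter
    nu_b=0.63,          # bottleneck size relative to N_ref
    nu_f=13.72,         # final size relative to N_ref
    t_b=0.164,          # epoch durations in 2 N_ref generations
    t_f=0.179,
    mu=1e-8,            # mutations / bp / generation
    length=5_806_952,   # callable bp
    f=0.9,              # inbreeding coefficient (passed through)
)
rep = rescale_demography(est)
print(f"N_ref = theta / (4 mu L) = {rep.n_ref:.1f} individuals")
print(f"bottleneck size N_B = {rep.n_b:.0f}, final size N_F = {rep.n_f:.0f}")
print(f"epoch times: T_B = {rep.t_b_gen:.1f}, T_F = {rep.t_f_gen:.1f} generations")
print(f"total time since the bottleneck: {rep.total_bottleneck_gen:.1f} generations")

# When the optimizer output is already rescaled to generations, the total is
# a plain sum:
total = total_bottleneck_time(96.52, 105.14)
print(f"\ntotal from already-rescaled epoch times 96.52 + 105.14 = {total:.2f} generations")
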