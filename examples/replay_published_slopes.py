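"""Recompute the published conditional slopes from printed coefficients.

Given the published standardized coefficients (B1 for the emotion, B3
for the emotion x severity product) and the severity descriptives
(M = 1929.68, SD = 2325.36, observed minimum 77 cases/day), the simple
slope at any severity level is B1 + B3*z.  The high level is M + 1SD
(z = +1); the low level substitutes the observed minimum because
M - 1SD is negative for this skewed series (z ~= -0.80).
"""

from emoprosocial import replay_table2

df = replay_table2()
print(df[["emotion", "level", "moderator_raw", "moderator_z", "slope"]]
      .round(3).to_string(index=False))

print("\nAnger at high severity: slope 1.22 — anger predicts prosocial")
print("expression strongly when the epidemic is severe. Sadness and")
print("surprise flip sign between the two severity levels, the signature")
print("of the moderation the interaction coefficients encode.")
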