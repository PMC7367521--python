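# Versioned phrasebook of synthetic key-risk marker phrases.
# The corpus generator embeds one of these phrases whenever a latent risk
# label is true, and the machine coder recovers labels by exact phrase
# lookup, which keeps coding deterministic and ground truth recoverable.
# Constraint: no phrase may be a substring of another (checked at load).
version: 1
markers:
  misuse:
    - took an extra dose without asking my doctor
    - used my leftover pills for this headache
    - borrowed a few from my wife's prescription
    - doubled my dose so i could sleep
  abuse:
    - crushed and snorted a couple to get high
    - chasing that euphoric rush again
    - took them just for the buzz
    - been railing these for the high
  addiction:
    - cannot function without it anymore
    - the withdrawals are tearing me apart
    - my tolerance keeps climbing every month
    - been hooked on these for years
  overdose:
    - wound up in the er after taking way too many
    - took a dangerous amount and blacked out
    - needed narcan after last night
  death:
    - my friend passed away from taking
    - it killed my brother last year
    - he was found dead with a patch on
    - we lost him to an od last spring
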