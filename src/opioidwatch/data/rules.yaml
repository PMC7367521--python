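# Exclusion rule configuration: rule order, metadata allow-lists and the
# phrase lists that approximate the study-style manual screening pass.
version: 1
order:
  - out_of_window
  - non_english
  - non_us
  - bad_source
  - off_context
  - spam
  - pharmacy_news_popculture
  - indeterminate
allowed_languages: [en]
allowed_countries: [US]
phrases:
  off_context:
    - trivia night question
    - name of the band
    - crossword puzzle answer
  spam:
    - no prescription needed
    - overnight shipping discreet
    - cheap pills online
    - limited time offer
  pharmacy_news_popculture:
    - breaking news report
    - episode recap
    - press release issued
    - new single dropped
  indeterminate:
    - qwerty asdf
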