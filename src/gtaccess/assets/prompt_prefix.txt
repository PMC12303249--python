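Did this breast cancer patient have access to germline genetic testing (testing done, recommended, or a genetic counseling referral made)? Reply with one of: Yes, No, Not applicable (all care in the community), Not sure (considered but criteria not met).

ANSWER: <Yes | No | Not applicable | Not sure>
RATIONALE: <one short sentence>

Clinical note excerpts:
{{document}}
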