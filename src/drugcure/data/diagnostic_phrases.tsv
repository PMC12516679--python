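# Phrases in an indication paragraph that mark a non-therapeutic
# (diagnostic/imaging) use; matched case-insensitively.
diagnostic agent
imaging agent
contrast agent
irrigating solution
cleansing
detection
gastrointestinal lavage
disclosing agent
sedation
echocardiograph
ultrasonograph
tomograph
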