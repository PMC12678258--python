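# token<TAB>replacement lexicon for the synonym-replacement augmentation
community	neighborhood
resilience	robustness
emergency	crisis
hospital	clinic
response	reaction
capacity	capability
framework	structure
indicator	measure
assessment	evaluation
infrastructure	facilities
health	wellbeing
disaster	catastrophe
preparedness	readiness
support	assistance
network	system
resource	asset
planning	design
recovery	restoration
risk	hazard
urban	city
public	civic
medical	clinical
space	area
green	vegetated
service	provision
management	administration
communication	messaging
population	residents
vulnerable	atrisk
training	education
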