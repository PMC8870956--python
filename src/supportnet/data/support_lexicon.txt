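# Seed vocabularies for the three social-support categories.
# Informational support: facts, suggestions, guidance (treatments, symptoms,
# clinicians, insurance). Emotional support: understanding, encouragement,
# empathy, affection, caring. Companionship: everyday chat, humor, daily life.
# Format: [category] headers, one word (or underscore-joined phrase) per line.

[informational]
treatment
treatments
chemo
chemotherapy
radiation
radiation_therapy
surgery
diagnosis
diagnosed
oncologist
doctor
doctors
physician
hospital
clinic
medication
medications
drug
drugs
dose
dosage
side_effects
side_effect
symptom
symptoms
scan
scans
mri
biopsy
blood_test
insurance
medical_insurance
trial
trials
prognosis
stage
tumor
tumors
cells
marker
markers
test
tests
results
monitoring
therapy
specialist
referral
appointment
screening

[emotional]
hope
hopeful
love
loved
hug
hugs
prayer
prayers
praying
courage
strength
strong
brave
fear
afraid
scared
anxious
anxiety
worried
worry
sad
sadness
cry
crying
happy
happiness
grateful
thankful
blessed
comfort
comforting
caring
empathy
compassion
encourage
encouragement
support
supportive
feelings
feeling
pain
painful
awful
terrible
overwhelmed
depressed
depression
relief
peace

[companionship]
birthday
holiday
holidays
christmas
thanksgiving
weekend
weather
garden
gardening
cooking
recipe
recipes
diet_plans
coffee
tea
movie
movies
book
books
music
walk
walking
travel
trip
vacation
family
friends
neighbor
neighbors
dog
cat
pets
grandchildren
grandkids
dinner
lunch
breakfast
game
games
scrabble
joke
jokes
funny
laugh
laughing
chat
chatting
hobby
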