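"""Name pools for the synthetic population.

Common Anglo-Australian surnames and given names; drawn with a
Zipf-skewed frequency so that, as in real administrative data, a small
set of very common names dominates and distinct persons occasionally
share the letter component of an SLK-581.
"""

SURNAMES = [
    "Smith", "Jones", "Williams", "Brown", "Wilson", "Taylor", "Johnson",
    "White", "Martin", "Anderson", "Thompson", "Nguyen", "Thomas", "Walker",
    "Harris", "Lee", "Ryan", "Robinson", "Kelly", "King", "Davis", "Wright",
    "Evans", "Roberts", "Green", "Hall", "Wood", "Jackson", "Clarke",
    "Young", "Allen", "Hill", "Scott", "Mitchell", "Murphy", "Moore",
    "Adams", "Baker", "Bell", "Campbell", "Carter", "Collins", "Cook",
    "Cooper", "Edwards", "Fisher", "Ford", "Foster", "Fraser", "Gibson",
    "Graham", "Grant", "Gray", "Hamilton", "Harvey", "Hayes", "Henderson",
    "Hughes", "Hunt", "Hunter", "James", "Jenkins", "Kennedy", "Lewis",
    "Lloyd", "Marshall", "Mason", "Matthews", "McDonald", "Miller",
    "Morgan", "Morris", "Murray", "Newman", "O'Brien", "O'Connor",
    "Palmer", "Parker", "Pearce", "Perry", "Phillips", "Powell", "Price",
    "Reid", "Richards", "Richardson", "Rogers", "Rose", "Ross", "Russell",
    "Shaw", "Simpson", "Stevens", "Stewart", "Stone", "Sullivan", "Turner",
    "Wallace", "Ward", "Watson", "Webb", "Wells", "West", "Wheeler",
    "Barnes", "Bennett", "Berry", "Black", "Boyd", "Bradley", "Brooks",
    "Burns", "Butler", "Byrne", "Cameron", "Chapman", "Cole", "Coleman",
    "Cox", "Crawford", "Cunningham", "Curtis", "Dawson", "Dean", "Dixon",
    "Douglas", "Doyle", "Duncan", "Dunn", "Elliott", "Ellis", "Ferguson",
    "Field", "Fleming", "Fletcher", "Fox", "Francis", "Freeman", "Gardner",
    "Gibbs", "Gordon", "Gregory", "Griffin", "Griffiths", "Hart", "Hawkins",
    "Holland", "Holmes", "Hopkins", "Howard", "Hudson", "Jordan", "Kaur",
    "Knight", "Lambert", "Lane", "Lawrence", "Lawson", "Long", "Lowe",
    "Lynch", "Macdonald", "Mann", "May", "McCarthy", "McKenzie", "Mills",
    "Moran", "Neville", "Nicholson", "Nolan", "Osborne", "Page", "Payne",
    "Peters", "Porter", "Read", "Reynolds", "Riley", "Robertson", "Saunders",
    "Sharp", "Singh", "Spencer", "Steele", "Stephens", "Sutton", "Walsh",
    "Warren", "Waters", "Watts", "Webster", "Wong",
]

GIVEN_NAMES = [
    "John", "Margaret", "Peter", "Mary", "David", "Patricia", "Robert",
    "Elizabeth", "Michael", "Joan", "William", "Judith", "Ronald", "Helen",
    "Kevin", "Dorothy", "Brian", "Shirley", "Graham", "Beryl", "James",
    "Joyce", "Kenneth", "Jean", "Raymond", "Betty", "Frank", "Barbara",
    "George", "Valerie", "Thomas", "Pamela", "Geoffrey", "Gwen", "Alan",
    "Norma", "Ian", "Lorraine", "Richard", "Carol", "Donald", "June",
    "Edward", "Marjorie", "Colin", "Nancy", "Gordon", "Fay", "Arthur",
    "Gloria", "Leslie", "Thelma", "Neil", "Doris", "Bruce", "Phyllis",
    "Maxwell", "Edna", "Stanley", "Olive", "Henry", "Ruth", "Albert",
    "Lillian", "Charles", "Vera", "Francis", "Sylvia", "Douglas", "Irene",
    "Norman", "Audrey", "Harold", "Eileen", "Walter", "Gladys", "Eric",
    "Alice", "Roy", "Florence", "Ernest", "Ethel", "Frederick", "Mavis",
    "Leonard", "Daphne", "Herbert", "Hazel", "Sidney", "Elsie", "Reginald",
    "Freda", "Clarence", "Ivy", "Lawrence", "Muriel", "Victor", "Agnes",
    "Stephen", "Christine", "Paul", "Susan", "Mark", "Jennifer", "Andrew",
    "Linda", "Philip", "Sandra", "Gregory", "Robyn", "Terry", "Kathleen",
    "Barry", "Wendy", "Wayne", "Denise", "Gary", "Janice", "Dennis",
    "Maureen", "Trevor", "Yvonne", "Rodney", "Lynette", "Allan", "Diane",
    "Bernard", "Anne", "Maurice", "Rosemary", "Cecil", "Heather", "Clive",
    "Dawn", "Roger", "Julie", "Noel", "Gail", "Keith", "Marion", "Samuel",
    "Janet", "Patrick", "Sharon", "Martin", "Beverley", "Anthony", "Lesley",
    "Joseph", "Veronica", "Daniel", "Frances", "Matthew", "Catherine",
    "Simon", "Deborah", "Christopher", "Angela", "Timothy", "Karen",
    "Nicholas", "Michelle", "Benjamin", "Fiona", "Adam", "Rebecca",
    "Joshua", "Claire", "Luke", "Emma", "Ahmed", "Mei", "Giovanni", "Sofia",
    "Dimitri", "Elena", "Hans", "Ingrid", "Pierre", "Chantal",
]
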